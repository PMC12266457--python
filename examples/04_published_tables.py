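"""Recompute scalar metrics from published pixel confusion tables.

The confusion counts of two burnt-area models over a ~32.4-million-pixel
study area are fed through the metric suite, reproducing every derived
figure (precision, recall, accuracy, dice, burnt-class IoU, normalized
confusion rows, burnt-area percentages and hectares) at full precision.
"""

from burntseg import ConfusionCounts, burnt_fraction, metrics, normalized_confusion
from burntseg.evaluation import pixels_to_hectares

tables = {
    "UNET": ConfusionCounts(tp=4_719_050, fp=199_264, fn=365_344, tn=27_101_423),
    "UNET-GRU": ConfusionCounts(tp=4_911_715, fp=142_747, fn=172_679,
                                tn=27_157_940),
}

for name, conf in tables.items():
    m = metrics(conf)
    n = normalized_confusion(conf)
    print(f"{name}  (total {conf.total:,} px)")
    print(f"  precision {m['precision']:.3f}  recall {m['recall']:.3f}  "
          f"accuracy {m['accuracy']:.3f}  dice {m['dice']:.3f}  "
          f"burnt-IoU {m['iou_burnt']:.3f}")
    print(f"  normalized confusion: tn {n['tn']:.3f}  fp {n['fp']:.3f}  "
          f"fn {n['fn']:.3f}  tp {n['tp']:.3f}")
    print(f"  burnt share: reference {burnt_fraction(conf, 'reference'):.1f} %, "
          f"predicted {burnt_fraction(conf, 'predicted'):.2f} %")

print(f"3,711,195 px at 3 m = {pixels_to_hectares(3_711_195, 3.0):.2f} ha "
      "(pixel area 9 m^2; 1 ha = 10,000 m^2)")
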