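model,precision,recall,f1,accuracy,iou_burnt,iou_macro,dice,auc_pooled
unet,0.9613122872175797,0.9669987546699875,0.9641471364271302,0.988720703125,0.930776146239137,0.9587402084942662,0.9641471364271302,0.9970339214683412
unet_gru,0.9627985303123087,0.9789850560398505,0.9708243284964495,0.990771484375,0.943302834858257,0.9662001757574143,0.9708243284964495,0.9971344446540669
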