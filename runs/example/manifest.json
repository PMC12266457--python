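{
 "config": {
  "seed": 1,
  "out_dir": "runs/example",
  "n_scenes": 3,
  "scene": {
   "height": 256,
   "width": 256,
   "burnt_fraction_target": 0.157,
   "n_burnt_patches": 5,
   "n_water_bodies": 1,
   "n_shadow_regions": 2,
   "patch_scale": 40.0,
   "fragmentation": 0.15,
   "class_spectra": {
    "vegetation": {
     "nir": [
      0.45,
      0.05
     ],
     "red": [
      0.06,
      0.015
     ],
     "green": [
      0.09,
      0.015
     ],
     "blue": [
      0.04,
      0.01
     ]
    },
    "burnt": {
     "nir": [
      0.12,
      0.025
     ],
     "red": [
      0.07,
      0.015
     ],
     "green": [
      0.06,
      0.012
     ],
     "blue": [
      0.04,
      0.01
     ]
    },
    "water": {
     "nir": [
      0.02,
      0.008
     ],
     "red": [
      0.03,
      0.008
     ],
     "green": [
      0.04,
      0.008
     ],
     "blue": [
      0.04,
      0.008
     ]
    },
    "shadow": {
     "nir": [
      0.08,
      0.015
     ],
     "red": [
      0.04,
      0.01
     ],
     "green": [
      0.04,
      0.01
     ],
     "blue": [
      0.03,
      0.008
     ]
    },
    "nonforest": {
     "nir": [
      0.3,
      0.04
     ],
     "red": [
      0.25,
      0.04
     ],
     "green": [
      0.22,
      0.03
     ],
     "blue": [
      0.18,
      0.03
     ]
    }
   },
   "noise_sd": 0.01,
   "coarse_pixel_size_m": 10.0,
   "pixel_size_m": 3.0,
   "seed": 0
  },
  "reference_mask": {
   "n_burnt_samples": 200,
   "n_unburnt_samples": 200
  },
  "bands": [
   "nir",
   "red",
   "green",
   "blue"
  ],
  "tile": 64,
  "split": {
   "train": 0.6,
   "test": 0.2,
   "validation": 0.2,
   "seed": 0,
   "prefer_burnt_train": true
  },
  "augmentation": null,
  "model": {
   "base_filters": 8,
   "depth": 3,
   "gru_units": null,
   "dropout": 0.2,
   "kernel": 3
  },
  "training": {
   "epochs": 30,
   "batch_size": 4,
   "lr0": 0.005,
   "plateau_factor": 0.9,
   "plateau_patience": 10,
   "min_lr": 1e-07,
   "early_stop_patience": 30,
   "seed": 0
  }
 },
 "config_sha256": "5186c8e28bae221c3aeff68455d6ab810ece088eb126e2647d948b2d0041ef31",
 "seed": 1,
 "versions": {
  "burntseg": "0.1.0",
  "numpy": "2.4.6",
  "pandas": "2.3.3"
 }
}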