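{
 "architecture": "custom_unet",
 "input_hw": [
  64,
  64
 ],
 "in_channels": 4,
 "n_classes": 2,
 "base_filters": 8,
 "depth": 3,
 "gru_units": null,
 "dropout": 0.2,
 "kernel": 3,
 "seed": 703768060,
 "dtype": "float32"
}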