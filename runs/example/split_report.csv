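category,burnt_pixels,burnt_ha,unburnt_pixels,unburnt_ha
Train,20308,18.2772,98476,88.6284
Test,6424,5.7816,34536,31.0824
Validation,4467,4.0203,32397,29.1573
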