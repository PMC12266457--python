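model,tn,fp,fn,tp
unet,34286,250,212,6212
unet_gru,34293,243,135,6289
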