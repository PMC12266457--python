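tile_id,auc_unet,auc_unet_gru
0,0.9951226957324518,0.995660606331338
15,0.9984253162363542,0.99876754461965
26,0.989699533448368,0.989233499768648
27,0.9960592887284281,0.996538656508099
28,0.9991452262612481,0.9997177825423124
29,0.9988116118409278,0.9995346672871103
32,0.9983616540045236,0.9976947166966306
39,0.9848788929707928,0.9859227054057276
42,0.9965984045826966,0.9946859453763222
45,0.9986684300360587,0.9985983474063775
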