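predictor,fm,bmc,lst
height,-0.0857,0.0032,0.0820
weight,0.3139,0.0392,0.6419
sk_suprailiac,0.1970,-0.0095,-0.1964
sk_horiz_abdominal,0.2350,-0.0105,-0.2321
phv,-0.6571,0.0525,0.7047
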