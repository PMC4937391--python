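subject,initial_tre_mm,updated_tre_mm
1,2.1,1.8
2,1.4,0.8
3,1.7,0.8
4,3.1,0.8
5,2.0,1.4
6,3.1,0.9
7,2.7,1.0
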