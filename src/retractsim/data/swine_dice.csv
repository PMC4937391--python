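subject,dice_pct
1,90.2
2,85.3
3,92.6
4,94.5
5,82.8
6,88.5
7,88.5
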