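digit,count
1,42
2,29
3,26
4,16
5,12
6,9
7,13
8,7
9,5
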