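digit,count
1,65
2,32
3,21
4,10
5,21
6,4
7,11
8,5
9,4
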