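digit,count
1,47
2,27
3,18
4,14
5,10
6,11
7,4
8,4
9,6
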