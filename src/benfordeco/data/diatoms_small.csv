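digit,count
1,32
2,15
3,9
4,11
5,7
6,12
7,6
8,7
9,6
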