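digit,count
1,48
2,26
3,27
4,19
5,5
6,7
7,4
8,4
9,8
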