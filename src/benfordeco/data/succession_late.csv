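digit,count
1,64
2,36
3,28
4,22
5,10
6,19
7,13
8,7
9,9
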