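digit,count
1,188
2,107
3,81
4,63
5,39
6,44
7,34
8,24
9,24
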