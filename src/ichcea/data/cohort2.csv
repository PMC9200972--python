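mrs,count
0,24
1,124
2,181
3,194
4,221
5,162
6,249
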