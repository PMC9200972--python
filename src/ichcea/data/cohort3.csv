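mrs,count
0,0
1,0
2,9
3,16
4,60
5,124
6,34
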