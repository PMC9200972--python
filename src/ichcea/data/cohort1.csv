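mrs,count
0,5
1,21
2,12
3,25
4,32
5,6
6,87
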