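from_mrs,to_mrs0,to_mrs1,to_mrs2,to_mrs3,to_mrs4,to_mrs5,to_mrs6
0,4,1,0,0,0,0,0
1,0,20,0,0,1,0,0
2,0,2,9,0,0,0,1
3,0,1,5,17,1,0,1
4,0,0,0,5,26,1,0
5,0,0,0,0,0,6,0
6,0,0,0,0,0,0,87
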