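from_mrs,to_mrs0,to_mrs1,to_mrs2,to_mrs3,to_mrs4,to_mrs5,to_mrs6
0,4,0,0,0,0,0,0
1,0,23,0,0,0,0,1
2,1,3,9,1,0,0,0
3,0,0,2,20,0,0,0
4,0,0,0,2,20,5,1
5,0,0,0,0,0,7,0
6,0,0,0,0,0,0,89
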