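mrs,mean,lower95,upper95
0,0.971,0.935,1.0
1,0.875,0.862,0.888
2,0.742,0.709,0.775
3,0.553,0.521,0.586
4,0.199,0.167,0.231
5,-0.186,-0.227,-0.146
6,0.0,0.0,0.0
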