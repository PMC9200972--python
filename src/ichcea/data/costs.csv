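mrs,phase,mean,lower95,upper95
0,1,16012,8536,26707
0,2,1569,546,3355
0,3,197,162,236
1,1,13026,7497,21375
1,2,3622,2232,5628
1,3,197,162,235
2,1,18447,12163,26970
2,2,6111,3679,9825
2,3,3482,968,7898
3,1,33952,21742,51012
3,2,12476,7836,19587
3,3,181,132,238
4,1,34237,25196,46305
4,2,11136,7048,16371
4,3,1521,195,5029
5,1,72303,43930,113159
5,2,28031,19521,38476
5,3,13269,8314,19285
6,1,5612,3920,7822
6,2,5.3,0,26.95
6,3,0,0,0
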