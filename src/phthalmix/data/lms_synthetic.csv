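sex,age_months,L,M,S
0,48,-1.6000,15.6000,0.0900
0,51,-1.5818,15.5498,0.0920
0,54,-1.5636,15.5083,0.0941
0,57,-1.5455,15.4754,0.0961
0,60,-1.5273,15.4512,0.0982
0,63,-1.5091,15.4357,0.1002
0,66,-1.4909,15.4289,0.1023
0,69,-1.4727,15.4308,0.1043
0,72,-1.4545,15.4413,0.1064
0,75,-1.4364,15.4605,0.1084
0,78,-1.4182,15.4884,0.1105
0,81,-1.4000,15.5250,0.1125
0,84,-1.3818,15.5702,0.1145
0,87,-1.3636,15.6242,0.1166
0,90,-1.3455,15.6868,0.1186
0,93,-1.3273,15.7581,0.1207
0,96,-1.3091,15.8380,0.1227
0,99,-1.2909,15.9267,0.1248
0,102,-1.2727,16.0240,0.1268
0,105,-1.2545,16.1300,0.1289
0,108,-1.2364,16.2446,0.1309
0,111,-1.2182,16.3680,0.1330
0,114,-1.2000,16.5000,0.1350
1,48,-1.6000,15.7500,0.0850
1,51,-1.5818,15.6998,0.0870
1,54,-1.5636,15.6583,0.0891
1,57,-1.5455,15.6254,0.0911
1,60,-1.5273,15.6012,0.0932
1,63,-1.5091,15.5857,0.0952
1,66,-1.4909,15.5789,0.0973
1,69,-1.4727,15.5808,0.0993
1,72,-1.4545,15.5913,0.1014
1,75,-1.4364,15.6105,0.1034
1,78,-1.4182,15.6384,0.1055
1,81,-1.4000,15.6750,0.1075
1,84,-1.3818,15.7202,0.1095
1,87,-1.3636,15.7742,0.1116
1,90,-1.3455,15.8368,0.1136
1,93,-1.3273,15.9081,0.1157
1,96,-1.3091,15.9880,0.1177
1,99,-1.2909,16.0767,0.1198
1,102,-1.2727,16.1740,0.1218
1,105,-1.2545,16.2800,0.1239
1,108,-1.2364,16.3946,0.1259
1,111,-1.2182,16.5180,0.1280
1,114,-1.2000,16.6500,0.1300
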