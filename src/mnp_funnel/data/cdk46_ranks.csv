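compound,AutoDockTools,LeDock,Qvina,Smina,Vina,PLANTS,rDock
194143-57-2,2,11,12,12,12,10,13
205813-99-6,3,5,10,10,9,4,8
207305-65-5,20,18,14,17,14,24,23
223130-61-8,17,2,3,3,4,17,7
251343-62-1,4,16,14,15,18,15,14
CMNPD10652,23,17,19,21,20,11,16
CMNPD11585,7,3,1,1,1,8,4
CMNPD12908,24,24,24,24,24,25,3
CMNPD1346,21,7,8,4,8,6,9
CMNPD13472,6,8,4,7,3,21,5
CMNPD14214,22,15,6,9,6,22,20
CMNPD14217,9,10,2,2,2,5,6
CMNPD2018,15,22,19,20,19,20,24
CMNPD2744,18,4,7,5,7,2,10
CMNPD3195,5,25,21,19,22,19,17
CMNPD4645,16,6,14,14,15,3,11
CMNPD4920,10,9,11,11,10,7,12
CMNPD5678,14,13,9,8,11,14,18
CMNPD5679,13,23,25,25,25,13,25
CMNPD5682,12,20,22,22,21,18,15
CMNPD646,19,14,23,23,23,16,19
CMNPD7036,8,21,14,13,16,9,2
CMNPD7986,1,1,5,6,5,1,1
CMNPD8752,11,12,13,16,13,12,21
CMNPD9390,24,19,14,18,17,23,22
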