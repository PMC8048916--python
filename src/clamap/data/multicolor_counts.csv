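mouse_id,sex,region_a,region_b,region_c,region_d,A,B,C,D,AB,AC,AD,BC,BD,CD,ABC,ABD,ACD,BCD,ABCD
M58,F,PL,rRSP,cRSP,iRSP,676,667,218,187,255,72,75,120,123,75,59,83,41,68,38
M59,F,cRSP,PL,iRSP,rRSP,156,1012,203,305,87,59,36,99,179,105,41,30,26,84,18
M176,F,MOs,iRSP,ALM,MOp,482,434,330,280,131,47,62,11,23,60,7,14,14,2,1
M178,F,MOs,iRSP,ALM,MOp,398,292,393,354,92,36,79,6,33,75,6,19,17,7,5
M231,M,MOs,iRSP,ALM,MOp,590,255,525,430,98,79,64,12,20,142,2,6,28,3,1
M177,F,SSbfd,iRSP,AUDp,VISp,119,309,188,176,20,29,9,14,36,37,6,4,8,4,2
M179,F,SSbfd,iRSP,AUDp,VISp,87,363,109,210,23,6,5,15,51,22,6,3,1,6,1
M180,F,SSbfd,iRSP,AUDp,VISp,103,146,90,187,12,8,11,6,24,26,1,3,4,0,0
M228,M,SSbfd,iRSP,AUDp,VISp,65,212,185,182,14,15,17,14,33,46,7,6,7,7,2
BM12,M,VISp,iRSP,ACA,,141,318,274,,51,44,,74,,,,,,,
BM13,M,VISp,iRSP,ACA,,263,115,301,,27,81,,29,,,,,,,
M129,F,pSUB,iRSP,ENTl,,233,370,689,,79,15,,5,,,,,,,
BM05,F,pSUB,iRSP,ENTl,,330,284,538,,61,31,,5,,,,,,,
M130,F,pSUB,iRSP,ENTl,ENTm,178,254,73,343,44,6,87,2,46,20,4,10,4,3,3
BM07,F,pSUB,iRSP,ENTl,ENTm,312,225,563,450,54,46,89,14,16,87,8,9,20,3,2
M201,M,,iRSP,PL,ENTm,,388,411,325,,,,89,21,27,,,,9,
M205,M,,iRSP,PL,ENTm,,427,347,551,,,,77,28,30,,,,5,
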