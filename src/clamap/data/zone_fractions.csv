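region,rc_level,count_mean,count_sd,dorsal_pct,dorsal_sd,core_pct,core_sd,ventral_pct,ventral_sd
ALM,rostral,116,24,70,5,23,4,7,1
MOs,rostral,125,11,24,4,57,3,19,7
PL,rostral,171,74,25,8,51,5,24,8
MOp,rostral,90,14,62,6,31,3,7,3
ACA,rostral,74,3,10,4,47,9,43,5
rRSP,rostral,117,47,17,10,76,14,7,5
SSbfd,rostral,23,4,43,5,50,8,7,3
iRSP,rostral,73,23,5,2,90,0,5,2
AUDp,rostral,36,17,34,10,43,12,23,7
VISp,rostral,44,17,23,11,51,16,26,10
cRSP,rostral,32,8,6,6,80,3,14,3
ENTl,rostral,91,45,11,5,31,9,58,7
pSUB,rostral,51,13,9,4,65,15,26,12
ENTm,rostral,110,16,16,5,40,12,44,12
ALM,intermediate,62,12,87,4,8,2,5,2
MOs,intermediate,80,22,40,6,42,2,18,6
PL,intermediate,91,36,20,4,55,4,25,5
MOp,intermediate,60,15,81,8,13,4,6,4
ACA,intermediate,45,6,14,2,45,13,41,10
rRSP,intermediate,88,39,17,11,73,17,10,6
SSbfd,intermediate,16,5,64,7,30,7,6,2
iRSP,intermediate,46,16,5,1,90,0,5,1
AUDp,intermediate,26,3,40,6,37,7,23,10
VISp,intermediate,31,5,16,6,57,13,27,9
cRSP,intermediate,36,10,4,2,82,6,14,5
ENTl,intermediate,78,42,19,8,19,9,62,12
pSUB,intermediate,52,15,10,3,68,12,22,8
ENTm,intermediate,59,20,13,5,44,11,43,10
ALM,caudal,30,7,76,8,11,5,13,4
MOs,caudal,41,10,39,6,36,5,25,9
PL,caudal,44,26,30,10,41,12,29,2
MOp,caudal,27,5,79,5,13,5,8,2
ACA,caudal,25,2,21,10,30,11,49,1
rRSP,caudal,38,5,24,17,61,29,15,12
SSbfd,caudal,9,2,65,14,25,9,10,6
iRSP,caudal,29,10,5,1,90,0,5,1
AUDp,caudal,11,5,39,19,34,19,27,3
VISp,caudal,20,3,20,7,55,12,25,13
cRSP,caudal,26,3,7,4,71,18,21,20
ENTl,caudal,67,36,15,7,7,3,78,9
pSUB,caudal,30,5,13,6,55,18,32,14
ENTm,caudal,40,11,17,4,33,9,50,7
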