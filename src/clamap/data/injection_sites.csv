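region,ap_mm,ml_mm,dv_mm,tracers
ALM,2.5,1.5,-0.8,rAAV2-GFP
MOs,1.8,0.7,-0.5,FB
PL,1.7,0.5,-1.0,FB;rAAV2-GFP;CTB647
MOp,1.0,1.7,-0.8,rAAV2-tdTomato
ACA,0.5,0.3,-0.8,rAAV2-GFP
rRSP,-1.0,0.5,-0.5,CTB647;rAAV2-tdTomato
SSbfd,-1.0,2.8,-0.8,FB
iRSP,-1.5,0.3,-0.5,FB;CTB647;rAAV2-GFP;rAAV2-tdTomato
AUDp,-2.5,3.8,-1.0,rAAV2-GFP
VISp,-2.9,2.5,-0.5,FB;rAAV2-tdTomato
cRSP,-3.0,0.5,-3.0,rAAV2-GFP;FB
ENTl,-3.0,3.8,-3.0,rAAV2-GFP
pSUB,-4.0,2.0,-1.5,FB
ENTm,-4.6,3.0,-2.7,rAAV2-tdTomato
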