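label,x,y
Fp1,-0.5459,1.5563
Fp2,0.5474,1.5558
F7,-1.4625,0.8841
F3,-0.7198,0.7609
Fz,0.0039,0.7219
F4,0.7408,0.7760
F8,1.4612,0.8887
FC5,-1.2365,0.2986
FC1,-0.3909,0.2985
FC2,0.4030,0.3063
FC6,1.2427,0.3115
T7,-1.6498,-0.3140
C3,-0.7885,-0.1403
Cz,0.0040,-0.0912
C4,0.8084,-0.1313
T8,1.6546,-0.2921
TP9,-1.7657,-0.9592
CP5,-1.0764,-0.6295
CP1,-0.3451,-0.4596
CP2,0.3729,-0.4573
CP6,1.0973,-0.6072
TP10,1.7624,-0.9621
P7,-1.1199,-1.1356
P3,-0.5797,-0.8616
Pz,0.0031,-0.7762
P4,0.6011,-0.8483
P8,1.1280,-1.1282
O1,-0.3783,-1.4462
Oz,0.0014,-1.4439
O2,0.3844,-1.4448
FCz,0.0041,0.2996
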