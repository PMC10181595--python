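segment,side,mass_fraction,length_fraction,com_fraction,gyration_fraction
head_neck,center,0.0810,0.182,0.567,0.495
trunk,center,0.4970,0.288,0.500,0.406
upper_arm,left,0.0280,0.186,0.436,0.322
upper_arm,right,0.0280,0.186,0.436,0.322
forearm,left,0.0160,0.146,0.430,0.303
forearm,right,0.0160,0.146,0.430,0.303
hand,left,0.0060,0.108,0.506,0.297
hand,right,0.0060,0.108,0.506,0.297
thigh,left,0.1000,0.245,0.433,0.323
thigh,right,0.1000,0.245,0.433,0.323
shank,left,0.0465,0.246,0.433,0.302
shank,right,0.0465,0.246,0.433,0.302
foot,left,0.0145,0.152,0.500,0.475
foot,right,0.0145,0.152,0.500,0.475
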