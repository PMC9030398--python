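muscle,pcsa_min,pcsa_max,arm_flex_min,arm_flex_max,arm_ext_min,arm_ext_max,arm_rd_min,arm_rd_max,arm_ud_min,arm_ud_max,tension_min,tension_max
FCR,90,690,10,20,,,5,15,,,0.2,1.0
PL,30,150,20,30,,,0,10,,,0.2,1.0
FCU,40,850,10,20,,,,,15,25,0.2,1.0
ECU,180,650,,,0,10,,,20,30,0.2,1.0
ECRB,220,790,,,10,20,10,20,,,0.2,1.0
ECRL,140,500,,,5,15,20,30,,,0.2,1.0
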