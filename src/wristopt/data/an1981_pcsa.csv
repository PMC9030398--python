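muscle,source,mass_g,fiber_length_mm,tendon_length_mm,pennation_deg,volume_cm3,pcsa_mm2,arm_flex_mm,arm_ext_mm,arm_rd_mm,arm_ud_mm
FCR,an1981,,,,,,200,,,,
PL,an1981,,,,,,90,,,,
FCU,an1981,,,,,,47,,,,
ECU,an1981,,,,,,480,,,,
ECRB,an1981,,,,,,450,,,,
ECRL,an1981,,,,,,370,,,,
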