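muscle,source,mass_g,fiber_length_mm,tendon_length_mm,pennation_deg,volume_cm3,pcsa_mm2,arm_flex_mm,arm_ext_mm,arm_rd_mm,arm_ud_mm
ECU,an1981+lemay1996,,,,,,480,,6,,
ECRB,an1981+lemay1996,,,,,,450,,12,,
ECRL,an1981+lemay1996,,,,,,370,,7,,
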