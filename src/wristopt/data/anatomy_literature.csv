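muscle,source,mass_g,fiber_length_mm,tendon_length_mm,pennation_deg,volume_cm3,pcsa_mm2,arm_flex_mm,arm_ext_mm,arm_rd_mm,arm_ud_mm
FCR,ref01,7.40,76.40,188.00,,,91.60,,,,
FCR,ref02,,58.00,,,12.40,200.00,,,,
FCR,ref03,,52.00,,,,,,,,
FCR,ref04,35.00,49.00,,,,681.00,,,,
FCR,ref05,,63.00,244.00,3.00,,160.00,,,,
FCR,ref06,,164.00,,3.10,,199.00,,,,
FCR,ref07,,,,,,,,,,
FCR,ref08,,,,,,199.00,,,,
PL,ref01,3.40,89.20,247.00,,,36.10,,,,
PL,ref02,,57.00,,,5.10,90.00,,,,
PL,ref03,,50.00,,,,,,,,
PL,ref04,,,,,,,,,,
PL,ref05,,64.00,269.00,4.00,,60.00,,,,
PL,ref06,,134.00,,3.50,,69.00,,,,
PL,ref07,,,,,,,,,,
PL,ref08,,,,,,69.00,,,,
FCU,ref01,13.30,72.80,200.00,10.00,,173.00,,,,
FCU,ref02,,48.00,,,15.20,47.00,,,,
FCU,ref03,,42.00,,,,,,,,
FCU,ref04,49.70,56.00,,,,842.00,,,,
FCU,ref05,,51.00,265.00,12.00,,290.00,,,,
FCU,ref06,,228.00,,12.10,,342.00,,,,
FCU,ref07,,40.30,,15.50,26.80,631.90,,,,
FCU,ref08,,,,,,,,,,
ECU,ref01,8.90,45.60,137.00,11.00,,184.80,,,,
ECU,ref02,,45.00,,,14.90,480.00,,,,
ECU,ref03,,45.00,,,,,,,,
ECU,ref04,38.20,56.00,,,,644.00,,,,
ECU,ref05,,62.00,228.00,4.00,,210.00,,,,
ECU,ref06,,182.00,,3.50,,260.00,,,,
ECU,ref07,,,,,,,,,,
ECU,ref08,,,,,,260.00,,,,
ECRB,ref01,9.60,35.10,185.00,12.00,,258.80,,,,
ECRB,ref02,,53.00,,,15.80,450.00,,,,
ECRB,ref03,,61.00,,,,,,,,
ECRB,ref04,40.50,49.00,,,,781.00,,,,
ECRB,ref05,,59.00,222.00,9.00,,220.00,,,,
ECRB,ref06,,127.00,,8.90,,273.00,,,,
ECRB,ref07,,,,,,,,,,
ECRB,ref08,,,,,,273.00,,,,
ECRL,ref01,13.90,72.70,210.00,,,171.10,,,,
ECRL,ref02,,78.00,,,18.30,370.00,,,,
ECRL,ref03,,93.00,,,,,,,,
ECRL,ref04,47.40,90.00,,,,500.00,,,,
ECRL,ref05,,81.00,224.00,,,220.00,,,,
ECRL,ref06,,93.70,,2.50,,146.00,,,,
ECRL,ref07,,,,,,,,,,
ECRL,ref08,,,,,,,,,,
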