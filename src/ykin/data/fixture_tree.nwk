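((E1b-V13,E2-M75)E-M96,((G1-M342,G2a-P15)G-M201,((I1-M253,I2-M438)I-M170,(J1-M267,J2-M172)J-M304)IJ-M429,((R1a-M420,(R1b1-L21,R1b2-U106)R1b-M343)P-M45)K-M9)F-M89)ROOT;
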