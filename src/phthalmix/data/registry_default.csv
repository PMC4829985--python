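code,lod,correction_factor,mol_weight,group
MEP,0.39,0.66,194.18,single
MnBP,0.4,1.0,222.24,single
MiBP,0.26,1.0,222.24,single
MCPP,0.16,1.0,252.22,single
MBzP,0.11,0.72,256.25,single
MECPP,0.25,1.0,308.33,DEHP
MEHHP,0.32,1.0,294.34,DEHP
MEHP,0.9,1.0,278.34,DEHP
MEOHP,0.45,1.0,292.33,DEHP
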