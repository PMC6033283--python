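gene_id,coefficient
ABL1,-0.0171
AR,-0.0087
HDAC1,0.0553
IRF1,-0.0252
JUN,0.0211
PAK2,-0.0163
PRKCB,-0.0124
RELA,-0.0329
STAT1,-0.0441
SUMO1,0.0268
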