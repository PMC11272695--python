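tissue,water,neutral_lipid,phospholipid,protein,acidic_phospholipid
plasma,0.93,0.0035,0.00225,0.060,0.0
lung,0.81,0.0030,0.0090,0.090,0.0035
liver,0.74,0.0348,0.0252,0.120,0.0023
kidney,0.78,0.0207,0.0162,0.100,0.0024
gut,0.77,0.0487,0.0163,0.090,0.0024
spleen,0.79,0.0201,0.0198,0.090,0.0020
muscle,0.76,0.0238,0.0072,0.120,0.0015
adipose,0.18,0.7900,0.0020,0.020,0.0004
skin,0.72,0.0284,0.0111,0.160,0.0014
brain,0.77,0.0510,0.0565,0.080,0.0004
heart,0.76,0.0115,0.0166,0.100,0.0023
bone,0.44,0.0740,0.0011,0.200,0.0004
rest,0.75,0.0400,0.0100,0.100,0.0010
blood_cells,0.63,0.0017,0.0029,0.330,0.0005
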