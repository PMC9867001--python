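accession	database	name	length_residues	mass_da
Q4GWV4	Swiss-Prot	Defensin Cg-Defm (Cg-Def) (Mantle defensin)	65	7008
P0DUE1	Swiss-Prot	Stimulator of interferon genes protein (TIR-STING) (Probable NAD(+) hydrolase) (EC 3.2.2.6)	415	47031
Q6L6Q6	Swiss-Prot	Lysozyme (EC 3.2.1.17) (1,4-beta-N-acetylmuramidase) (Invertebrate-type lysozyme)	137	15274
Q20A05	Swiss-Prot	Hemocyte defensin Cg-Defh2 (Fragment)	60	6439
Q20A06	Swiss-Prot	Hemocyte defensin Cg-Defh1 (Fragment)	60	6587
Q7M456	Swiss-Prot	Ribonuclease Oy (RNase Oy) (EC 3.1.27.-)	213	24360
Q95WY0	Swiss-Prot	Tropomyosin (Allergen Cra g 1.03) (allergen Cra g 1) (Fragment)	233	26867
A9XE49	Swiss-Prot	Interleukin 17-like protein (CgIL-17)	200	21551
O17320	Swiss-Prot	Actin	376	41792
XP_034310988.1	NCBI RefSeq	Myosin Heavy Chain, Striated Muscle	1986	222660
XP_011429256.1	NCBI RefSeq	Paramyosin Isoform X2	886	102210
NP_001295835	NCBI RefSeq	Tropomyosin Isoform X1	284	33020
XP_011417566.1	NCBI RefSeq	Myosin Regulatory Light Chain B, Smooth Adductor Muscle Isoform X1	166	20580
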