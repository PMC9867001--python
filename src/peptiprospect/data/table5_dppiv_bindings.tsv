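sequence	receptor_id	predictor	predictor_score	rank	p_value	receptor_residues	peptide_residues
EQTQP	2ONC	iDPPIV-SCM	418.75	1	5.18e-3	Y48;W627;W629;V653;I703;I742;H748;I751;Y752;M755;Y547;S630;H740;G741	E1;Q2;T3;Q4;P5
TVPIY	2ONC	iDPPIV-SCM	389.25	2	1.78e-2	Y48;W627;W629;V653;I703;I742;H748;I751;Y752;M755;G741;F357;Y547;Y666	T1;V2;P3;I4;Y5
VDDLPPPL	2ONC	iDPPIV-SCM	385	3	6.52e-2	F357;Y547;P550;W629;Y631;Y666;Y670;G741;Y752;Y48;W627;H748	V1;D2;D3;L4;P5;P6;P7;L8
YPPVHDNN	2ONC	iDPPIV-SCM	373	4	3.23e-2	F357;Y547;P550;C551;Y585;W629;S630;Y631;Y662;Y666;Y670;H740;Y48;W627;H748;Y752;G741	Y1;P2;P3;V4;H5;D6;N7;N8
VAPEEHPVL	2ONC	iDPPIV-SCM	360	5	8.93e-2	F357;Y547;P550;W627;W629;S630;Y631;Y662;Y666;Y670;H740;Y752;Y48;M733;W734;Y735;H750;G741;H748	V1;A2;P3;E4;E5;H6;P7;V8;L9
NSPAM	2ONC	iDPPIV-SCM	359.25	6	1.22e-2	Y48;W627;W629;H740;Y752;H748;S630;Y631;V656;W659;Y662;Y666;Y547	N1;S2;P3;A4;M5
SVPVL	2ONC	iDPPIV-SCM	350	7	8.85e-3	Y48;W627;W629;H740;Y752;S630;G741;H748	S1;V2;P3;V4;L5
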