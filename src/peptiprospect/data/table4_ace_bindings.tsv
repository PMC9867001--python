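sequence	receptor_id	predictor	predictor_score	rank	p_value	receptor_residues	peptide_residues
CEPVY	1O86	AHTpin	1.44	1	6.94e-4	H353;H383;H387;F409;H410;E411;A412;I413;G414;D415;F457;K511;H513;Y523;S526;F527;Q281;A354;E384;Y520;S355;Y146;F512;A356	C1;E2;P3;V4;Y5
QQQIK	1O86	AHTpin	1.44	2	1.37e-4	Q281;H353;A354;H383	Q1;Q2;Q3;I4;K5
EVSETTCPR	1O86	AHTpin	1.43	3	6.96e-4	Q281;H353;A354;S355;A356;H383;E384;H387;F391;E411;F457;K511;H513;Y520;H410;R522;W59;Y360	E1;V2;S3;E4;T5;T6;C7;P8;R9
VAPEEHPVL	1O86	AHTpin	1.37	4	2.30e-4	Y146;W279;Q281;H353;H383;H387;H410;E411;A412;D415;F457;F460;K511;F512;H513;Y520;Y523;S526;F527;E384;A354;S355;A356;R522	V1;A2;P3;E4;E5;H6;P7;V8;L9
PQSCR	1O86	AHTpin	1.33	5	5.62e-5	W279;Q281;H353;H383;E411;D415;F457;F460;K511;H513;Y520;Y523;S526;F527;A354;E384;H387;F409;H410;A412;I413;G414;Q530	P1;Q2;S3;C4;R5
AQQQK	1O86	AHTpin	1.27	6	7.32e-5	Q281;H353;A354;H383;E384;H387;E411;F457;K511;H513;Y520;Y523;F527;W279;F460;F512	A1;Q2;Q3;Q4;K5
GPSSNPNF	1O86	AHTpin	1.17	7	1.07e-4	W279;Q281;H353;A354;S355;H383;E384;H387;E411;F457;F460;K511;H513;Y520;Y523;N66;A356;W357;F391;F512;D358;Y360;F527	G1;P2;S3;S4;N5;P6;N7;F8
EQTQP	1O86	AHTpin	1.14	8	2.71e-5	Q281;H353;A354;H383;E384;H387;E411;F457;F460;K511;H513;Y520;F527;F512;Y523;D415;S526;S355	E1;Q2;T3;Q4;P5
STHPH	1O86	AHTpin	1.02	9	5.55e-5	Q281;H353;A354;S355;H383;E384;H387;E411;F457;H513;Y520;Y523;K511;W279;F460	S1;T2;H3;P4;H5
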