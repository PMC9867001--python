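sequence	source_accession	shortlist_classes	AHTpin	iDPPIV-SCM	PreAIP	PreAIP_positive	Antiinflam	Antiinflam_positive	CAMP-SVM	CAMP-RF	ADAM	DBAASP_positive	ACPred	iDACP	mACPpred
CEPVY	A9XE49	AHP	1.44												
QQQIK	XP_034310988.1	AHP	1.44												
VAPEEHPVL	O17320	AHP;ADP	1.37	360											
AQQQK	XP_011417566.1	AHP	1.27												
STHPH	XP_034310988.1	AHP	1.02												
EVSETTCPR	Q7M456		1.43												
PQSCR	P0DUE1		1.33												
GPSSNPNF	XP_034310988.1		1.17												
EQTQP	XP_034310988.1	ADP	1.14	418.75											
YPPVHDNN	Q7M456	ADP		373											
NSPAM	O17320	ADP		359.25											
SVPVL	P0DUE1	ADP		350											
TVPIY	O17320			389.25											
VDDLPPPL	P0DUE1			385											
CTCTDCNGK	Q4GWV4	AIP;ACP			0.613	1		1					0.985	0.5574	0.9253
QACID	XP_034310988.1	AIP			0.534	1		1							
QEGCTCVR	A9XE49	AIP			0.521	1		1							
ICNEIK	P0DUE1	AIP			0.491	1	3.356	1							
EEESESASN	XP_011429256.1	AMP							1	0.6545					
EEASGM	XP_011429256.1	AMP							1	0.6395					
ETAANM	XP_011429256.1	AMP							1	0.554					
DKDGK	XP_011417566.1	AMP							1	0.5475					
SVVANNIK	Q95WY0	AMP										1			
CSGCVP	A9XE49	ACP											0.947	0.5196	0.9812
CQSIGCR	Q20A06	ACP											0.935	0.5196	0.8374
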