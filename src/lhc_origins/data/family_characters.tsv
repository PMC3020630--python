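taxon	HLIP	OHP1	OHP2	SEP	ELIP	RedCAP	LHC	PSBS
Gloeobacter	1	0	0	0	0	0	0	0
Synechocystis	1	0	0	0	0	0	0	0
Nostoc	1	0	0	0	0	0	0	0
Cyanophora	1	0	1	1	0	0	0	0
Glaucocystis	1	0	1	1	0	0	0	0
Cyanidioschyzon	1	0	1	0	0	1	1	0
Galdieria	1	0	1	1	0	1	1	0
Phaeodactylum	1	0	1	1	0	1	1	0
Thalassiosira	1	0	1	1	0	1	1	0
Chlamydomonas	0	1	1	1	1	0	1	1
Ostreococcus	0	1	1	1	1	0	1	1
Physcomitrella	0	1	1	1	1	0	1	1
Pinus	0	1	1	1	1	0	1	1
Oryza	0	1	1	1	1	0	1	1
Arabidopsis	0	1	1	1	1	0	1	1
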