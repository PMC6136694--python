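species	locus	component	pas	residues
Bacillus subtilis	KinA	kinase	yes	TAGFQL
Bacillus subtilis	KinB	kinase	no	TVGFQL
Bacillus subtilis	KinC	kinase	yes	TSGFQI
Bacillus subtilis	KinD	kinase	no	TGGFQL
Bacillus subtilis	KinE	kinase	yes	TAGFQL
Bacillus subtilis	Spo0F	spo0f		QGILEVD
Bacillus subtilis	Spo0B	spo0b		QLGNSL
Bacillus subtilis	Spo0A	spo0a		NELLEYD
Desulfotomaculum acetoxidans	Dtox_0091	kinase	yes	TTGFQM
Desulfotomaculum acetoxidans	Dtox_1564	kinase	no	TAAFEL
Desulfotomaculum acetoxidans	Dtox_1918	kinase	yes	TTGFQL
Desulfotomaculum acetoxidans	Dtox_2569	kinase	yes	TTGFQM
Desulfotomaculum acetoxidans	Dtox_3081	kinase	yes	TTGFQF
Desulfotomaculum acetoxidans	Dtox_3426	kinase	yes	TTGFQL
Desulfotomaculum acetoxidans	Dtox_3834	kinase	yes	TTGFQM
Desulfotomaculum acetoxidans	Spo0F	spo0f		QGILEVD
Desulfotomaculum acetoxidans	Spo0B	spo0b		QVGLQL
Desulfotomaculum acetoxidans	Spo0A	spo0a		NEFLDFD
Clostridium acetobutylicum	CA_C0323	kinase	no	NVSAQV
Clostridium acetobutylicum	CA_C0903	kinase	yes	NISAQL
Clostridium acetobutylicum	CA_C3319	kinase	no	SVGLQL
Clostridium acetobutylicum	Spo0A	spo0a		NEFIDYD
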