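construct	role	residues
BsKinA	HISKA_LIKE	TAGFQL
Bs0F	REC	QGILEVD
Bs0B	HISKA_LIKE	QLGNSL
Bs0A	REC	NELLEYD
Dt1918	HISKA_LIKE	TTGFQL
Dt0F	REC	QGILEVD
Dt0B	HISKA_LIKE	QVGLQL
Dt0A	REC	NEFLDFD
Ca0903	HISKA_LIKE	NISAQL
Ca3319	HISKA_LIKE	SVGLQL
Ca0A	REC	NEFIDYD
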