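field	name	value
profile	hiska_synthetic	HISKA_LIKE
anchor	EnvZ_like	20
anchor	RstB_like	20
anchor	CpxA_like	20
offset	0	3
offset	1	4
offset	2	7
offset	3	8
offset	4	11
offset	5	12
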