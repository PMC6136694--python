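field	name	value
profile	rec_synthetic	REC
anchor	OmpR_like	55
anchor	RstA_like	55
anchor	CpxR_like	55
offset	0	5
offset	1	6
offset	2	9
offset	3	10
offset	4	13
offset	5	56
offset	6	57
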