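protein_a	protein_b	lls
P3	P6	1.663505133704376
P3	P4	1.663505133704376
P4	P6	1.663505133704376
P4	P7	1.663505133704376
P3	P8	1.663505133704376
P6	P8	1.663505133704376
P5	P7	1.663505133704376
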