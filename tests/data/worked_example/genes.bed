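chrS1	0	20000	P1	0	+
chrS1	50000	70000	P2	0	+
chrS1	100000	120000	P3	0	+
chrS1	150000	170000	P4	0	+
chrS1	200000	220000	P5	0	+
chrS1	250000	270000	P6	0	+
chrS1	300000	320000	P7	0	+
chrS1	350000	370000	P8	0	+
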