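PWY1	PWY1	P1	P2	P3
PWY2	PWY2	P4	P5	P7
PWY3	PWY3	P3	P6	P8
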