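D1	PWY1	+
D2	PWY2	+
D3	PWY3	+
D1	PWY2	-
D1	PWY3	-
D2	PWY1	-
D2	PWY3	-
D3	PWY1	-
D3	PWY2	-
D4	PWY1	-
D4	PWY2	-
D4	PWY3	-
D6	PWY1	-
D6	PWY2	-
D6	PWY3	-
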