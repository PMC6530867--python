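protein_id	domain_id
P1	D1
P1	D2
P1	D3
P1	D4
P1	D5
P2	D1
P2	D4
P2	D5
P2	D6
P3	D1
P3	D3
P3	D4
P3	D6
P4	D2
P4	D4
P4	D5
P5	D1
P5	D2
P5	D4
P5	D5
P5	D6
P6	D1
P6	D3
P6	D4
P6	D6
P7	D2
P7	D4
P7	D5
P7	D6
P8	D3
P8	D4
P8	D6
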