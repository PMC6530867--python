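domain_a	domain_b
D1	D3
D1	D5
D2	D3
D2	D4
D2	D5
D3	D5
D4	D5
D5	D6
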