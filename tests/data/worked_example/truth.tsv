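domain_id	truth
D1	planted-PSD
D2	planted-PSD
D3	planted-PSD
D4	decoy
D5	decoy
D6	decoy
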