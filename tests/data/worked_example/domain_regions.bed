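chrS1	0	300	D1|PSD	0	+
chrS1	300	600	D2|PSD	0	+
chrS1	600	900	D3|PSD	0	+
chrS1	900	1200	D4|NSD	0	+
chrS1	1200	1500	D5|NSD	0	+
chrS1	50000	50300	D1|PSD	0	+
chrS1	50300	50600	D4|NSD	0	+
chrS1	50600	50900	D5|NSD	0	+
chrS1	50900	51200	D6|NSD	0	+
chrS1	100000	100300	D1|PSD	0	+
chrS1	100300	100600	D3|PSD	0	+
chrS1	100600	100900	D4|NSD	0	+
chrS1	100900	101200	D6|NSD	0	+
chrS1	150000	150300	D2|PSD	0	+
chrS1	150300	150600	D4|NSD	0	+
chrS1	150600	150900	D5|NSD	0	+
chrS1	200000	200300	D1|PSD	0	+
chrS1	200300	200600	D2|PSD	0	+
chrS1	200600	200900	D4|NSD	0	+
chrS1	200900	201200	D5|NSD	0	+
chrS1	201200	201500	D6|NSD	0	+
chrS1	250000	250300	D1|PSD	0	+
chrS1	250300	250600	D3|PSD	0	+
chrS1	250600	250900	D4|NSD	0	+
chrS1	250900	251200	D6|NSD	0	+
chrS1	300000	300300	D2|PSD	0	+
chrS1	300300	300600	D4|NSD	0	+
chrS1	300600	300900	D5|NSD	0	+
chrS1	300900	301200	D6|NSD	0	+
chrS1	350000	350300	D3|PSD	0	+
chrS1	350300	350600	D4|NSD	0	+
chrS1	350600	350900	D6|NSD	0	+
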