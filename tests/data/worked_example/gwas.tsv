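snp_id	chrom	pos	p
rs000001	chrS1	3880	5.387325020060215e-05
rs000002	chrS1	1452	0.45742569813821743
rs000003	chrS1	16322	0.08153146030257341
rs000004	chrS1	52423	2.458928467889742e-06
rs000005	chrS1	71288	0.7631809514014812
rs000006	chrS1	53991	0.1310789882913207
rs000007	chrS1	114217	3.6270932886605923e-06
rs000008	chrS1	97438	0.3064105792068602
rs000009	chrS1	117145	0.8327943100020676
rs000010	chrS1	172191	0.00014952061767079403
rs000011	chrS1	145589	0.3753740170194637
rs000012	chrS1	158044	0.7108815531965337
rs000013	chrS1	197104	0.6742009904352112
rs000014	chrS1	218294	0.37073279482625254
rs000015	chrS1	211015	0.06421200016610362
rs000016	chrS1	269773	0.19083820348967717
rs000017	chrS1	273283	0.2662372266129436
rs000018	chrS1	267724	0.5361200423793722
rs000019	chrS1	314147	0.18427021286649659
rs000020	chrS1	321897	0.7995369713881428
rs000021	chrS1	311760	0.6445216230234747
rs000022	chrS1	348773	8.265612489543476e-05
rs000023	chrS1	357159	0.8430250668415862
rs000024	chrS1	374903	0.777115809053182
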