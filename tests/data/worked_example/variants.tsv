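chrom	pos	class_label
chrS1	350058	pathogenic
chrS1	200260	pathogenic
chrS1	1389	pathogenic
chrS1	300746	pathogenic
chrS1	201138	pathogenic
chrS1	200586	pathogenic
chrS1	100454	pathogenic
chrS1	100627	pathogenic
chrS1	50218	pathogenic
chrS1	70	pathogenic
chrS1	300368	pathogenic
chrS1	150058	pathogenic
chrS1	200060	pathogenic
chrS1	100273	pathogenic
chrS1	250409	pathogenic
chrS1	32	pathogenic
chrS1	100354	pathogenic
chrS1	119	pathogenic
chrS1	704	pathogenic
chrS1	350394	pathogenic
chrS1	201485	pathogenic
chrS1	101160	pathogenic
chrS1	200172	pathogenic
chrS1	300596	pathogenic
chrS1	100103	pathogenic
chrS1	200342	pathogenic
chrS1	250082	pathogenic
chrS1	100327	pathogenic
chrS1	200286	pathogenic
chrS1	250366	pathogenic
chrS1	301034	pathogenic
chrS1	661	pathogenic
chrS1	350295	pathogenic
chrS1	48	pathogenic
chrS1	250455	pathogenic
chrS1	300286	pathogenic
chrS1	757	pathogenic
chrS1	101170	pathogenic
chrS1	300269	pathogenic
chrS1	231	pathogenic
chrS1	200823	neutral
chrS1	150209	neutral
chrS1	301141	neutral
chrS1	150223	neutral
chrS1	350264	neutral
chrS1	867	neutral
chrS1	150157	neutral
chrS1	200245	neutral
chrS1	350575	neutral
chrS1	50990	neutral
chrS1	300014	neutral
chrS1	250052	neutral
chrS1	250310	neutral
chrS1	201331	neutral
chrS1	350607	neutral
chrS1	100378	neutral
chrS1	100976	neutral
chrS1	50513	neutral
chrS1	375	neutral
chrS1	50585	neutral
chrS1	350057	neutral
chrS1	300592	neutral
chrS1	1071	neutral
chrS1	200974	neutral
chrS1	150612	neutral
chrS1	200992	neutral
chrS1	250178	neutral
chrS1	100033	neutral
chrS1	350350	neutral
chrS1	150335	neutral
chrS1	201404	neutral
chrS1	201227	neutral
chrS1	50007	neutral
chrS1	437	neutral
chrS1	150094	neutral
chrS1	251072	neutral
chrS1	300582	neutral
chrS1	250858	neutral
chrS1	1062	neutral
chrS1	350193	neutral
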