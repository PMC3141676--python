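# Published annotation-category counts per library (unique tags and redundant reads)
category	PT1_unique	PT1_total	PT2_unique	PT2_total	PT3_unique	PT3_total
total	718770	8924476	596498	5609466	672323	6982282
exon_antisense	6399	10386	12995	21742	16265	29367
exon_sense	132234	709873	157692	491026	126953	468933
intron_antisense	738	3668	1054	6759	1331	5795
intron_sense	3244	10084	3334	14835	3773	28637
known_miRNA	3660	36409	2821	36511	3573	44646
rRNA	187636	5580308	101013	2708557	129970	3837474
siRNA	499	1206	2032	6135	2483	7836
snRNA	395	1769	358	1843	384	3034
snoRNA	147	603	130	858	156	1381
tRNA	20630	798584	13200	445663	17783	703652
non_annotated	363188	1771586	301869	1875537	369652	1851527
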