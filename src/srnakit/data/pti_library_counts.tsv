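# Published per-library read accounting for the three P. tricornutum small-RNA libraries
# (normal, nitrogen-limited and silicon-limited cultures)
sample	total_srna	unique_srna	genome_total	genome_unique	chloroplast_total	chloroplast_unique	singleton_unique
PT1	8924476	718770	4105629	221523	3076974	68048	521761
PT2	5609466	596498	2492000	262038	1503395	43151	441959
PT3	6982282	672323	2908127	250371	2410100	55321	491748
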