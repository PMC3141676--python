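# Published characteristics of the 13 Phaeodactylum tricornutum pre-miRNAs (pti-miR5471..pti-miR5483)
# location is chrom:start:end:strand, 1-based inclusive; mfe in kcal/mol; len in nt
# homogeneity cells are "reads with the mature 5' end / reads mapped to the precursor" per library
name	location	mfe	len	p_value	PT1	PT2	PT3	bulges	mismatched
pti-miR5471	chr_1:1604545:1604822:-	-78.8	278	0.172	0/0	9/9	0/0	0	5
pti-miR5472	chr_10:761305:761625:-	-85.9	321	0.355	64/88	23/30	145/213	0	5
pti-miR5473	chr_11:35406:35506:-	-30.4	101	0.019	6/9	0/0	9/15	0	4
pti-miR5474	chr_15:663006:663165:+	-42.7	160	0.801	22/23	69/71	20/22	0	6
pti-miR5475	chr_18:415320:415541:-	-62	222	0.44	0/0	226/230	383/385	0	4
pti-miR5476	chr_19:299730:299870:-	-52.8	141	0.043	0/0	0/0	9/15	0	3
pti-miR5477	chr_1:2137385:2137503:-	-26.1	119	0.025	0/0	0/0	6/9	0	6
pti-miR5478	chr_23:97534:97765:+	-76.1	232	0.029	0/0	0/0	5/7	0	4
pti-miR5479	chr_25:444580:444846:+	-79.6	267	0.1	0/0	0/0	18/19	0	4
pti-miR5480	chr_26:278601:278960:+	-105	360	0.146	0/0	0/0	6/8	0	6
pti-miR5481	chr_2:1365749:1366009:+	-70.8	261	0.213	0/0	0/0	5/5	0	4
pti-miR5482	chr_9:128204:128523:+	-101	320	0.561	0/0	0/0	5/6	0	3
pti-miR5483	chr_9:523733:524013:+	-67.6	281	0.126	0/0	0/0	10/12	0	5
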