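# Published common/specific tag counts between every two libraries
pair	common_unique	a_specific_unique	b_specific_unique	common_total	a_specific_total	b_specific_total
PT1_PT2	173647	545123	422851	13293850	741310	498782
PT2_PT3	169588	426910	502735	11460968	497883	632897
PT1_PT3	200334	518436	471989	14690632	659616	556510
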