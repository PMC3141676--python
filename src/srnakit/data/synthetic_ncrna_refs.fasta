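>rRNA_SSU_1 class=rRNA source=genbank
ACGTTGTATACGACGGCGGCGCAGGGGATTTCGCTTCTGCCCTAAAAACTCTGGTAACCTCATCCCCAGCATGGGATCACCCTGCAAACGTCCTGGTAACTAGGACCCCCCGGCGTTATGAGCAATCCGCCTCTCTACATAATTCAGACA
>rRNA_LSU_1 class=rRNA source=genbank
GCGGTCATCCTCAAGCCCGATGCCCGAAACCGGAAGTCTGGACAGCGAGAATTGTAGGCTCGGTGTCGAACTCTGCTGTTCAACAATTGAACGATATCAGGTCCACGCAGTCCCTCCTTTACTGGCGTGGAGTAAATGCCACCCTCGCAGACGACGGATC
>rRNA_5S_1 class=rRNA source=rfam
ACCTTTTGACGATCGCGGAGGCAGGCTCAGAGGTCATCTGCCTGCGCATGTTCAGGGCCGCCATTAATCTTATGCGCCCCCTAGGAGTTCGAGGTTTGCTCGAGAGGGGCGGGACCGCA
>tRNA_Ala_1 class=tRNA source=genbank
GCCTGCAACTCTTAAGCATTGCTTTGGTTCCCACTCGAGGGTGACCTACGCGATCTTAATACGGGAATTACAG
>tRNA_Gly_1 class=tRNA source=rfam
AATTAAACTATGGTTGGCTCAGGGCCCGTGTGTTCACCTGAAGTAAGTCGTTGAGCTACCGGTCTGTCGGGT
>snRNA_U1_1 class=snRNA source=genbank
TCATTATTTCCGGGTAACTATCATGTATTCGCGGATCAATCCATGAGCCTCGGACACGTTCCTAAGACAACGATATAGGATAGCACCCGTGCTACCAGGAAATGGTATGA
>snRNA_U6_1 class=snRNA source=rfam
TTTAAATTTACTTATGGAACTTATTTATGCCAGTCGCGTACTTCTCAAAACTTCCGATAACGCTGTTCTGTTTCTGAAATTCCAAAACACAGCTTCCAACAGGC
>snoRNA_SNORD_1 class=snoRNA source=genbank
GTCAGTTGTCGGTGTAGCGGCAAATTTAAACAAGTCCCTTCGCATATTTATTGAACGGAGAGGCTGCTTGAAGACCGCCGTTTGGACATG
>snoRNA_SNORA_1 class=snoRNA source=rfam
GGAGGAGTGGTAGACGAAGTGTTCCGGCTACATTGCGTGAGATCAAGGTGTACGGCTATGAATGGAACAAACATTAAGAAATATCCACAGAAAGC
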