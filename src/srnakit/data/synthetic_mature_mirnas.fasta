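>syn-miR001 class=miRNA source=mirbase
CGGGGCGGGTATACAGCGCC
>syn-miR002 class=miRNA source=mirbase
GGAGTTTAAACAAAACGAAT
>syn-miR003 class=miRNA source=mirbase
ATTCATACTTAATCTCACGA
>syn-miR004 class=miRNA source=mirbase
GTCCTATTTTGCCGTCACCGCG
>syn-miR005 class=miRNA source=mirbase
GTACTAGTACACAGTGCACTG
>syn-miR006 class=miRNA source=mirbase
ACGCAGTGTATAAAAGACGG
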