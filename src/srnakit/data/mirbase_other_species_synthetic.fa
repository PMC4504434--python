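>ath-miR156a
TCTGAAAACATAGCGAAGACC
>ath-miR390a
TAGAGACAAGAATGCAGCGGA
>osa-miR160c
TTAGATACCTATCCCCGTCGT
>osa-miR396a
TTGACTTTGCGGACCCATCTC
>zma-miR166a
TGAATGCTTTTTTATCGCTTC
>zma-miR529
TCACCAGCGCCTGTCGTGAGG
>bdi-miR169a
TAACCAAACATTAACGAATCG
>ath-miR2118
TTCCAATGGGACGCGTCGCAA
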