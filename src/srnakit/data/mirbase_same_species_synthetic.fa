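>sbi-miR156a
TGTGAGTGACTCATCCCTTTC
>sbi-miR160a
TTGGAATATCGTTTCCTTTCT
>sbi-miR166b
TCAGTATGTCCCTGAAGACAA
>sbi-miR167d
TTTTCTCTATGATTCGGATGC
>sbi-miR169d
TCCAAACTAGATAGTCGCAGA
>sbi-miR390
TTACCTCAATCGAGTGTTATT
>sbi-miR396b
TGAATAGACACAATAACCTTA
>sbi-miR399a
TCTGTACGTTCCTAAAAAGCA
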