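>rRNA_5S_synthetic
ATGCTTGTTCCCTTGCCGTTTTGTTGTGAACACGAAGCACCGGAAGGCCCCGCCGTGAGGCGCCGTTGCTTCACATTACACGCCAAGACCTGCAGCCTAAAGTAGGTCTCACTTATGGGC
>rRNA_5.8S_synthetic
TACCCAGCCGTATCTCCAGGCAGTCTTGACGTTTGTGATGCCGGTAGCCGGCAGCGCGTCGCCCTCGTTCACGTGTAGGTCTCCGTAACTGTCAGTTTAACCGTTCCACTGCCCCCACCGGTGCAAGGCAACGGCCTCGCACACACGGCATGGAGGGATG
>tRNA_Ala_synthetic
TAGCGCAGCAGTGCGACGGGGGACATCCTAATAGCTCGGGCATACCACCAAAGAGGAGTTCCTTTTGGCCTCGGTG
>tRNA_Gly_synthetic
TCGCAGACAATACATGAATATGGCATGGAGCGGCGGAATTCCCCGGTTCTTGGGGGGTTTGTGATGAGAAGTAG
>rRNA_18S_fragment_synthetic
ATCCTTCCTGGTTAGTCGGTGATCGTTACCCTAAAAGGTTTGCTGTGATCTTAATTCCGAACTGCGGAGCGGCGCTTGCGCAGGGTGCTCGGGTACGCTTATTACAAGTTGTTCACGGGTCTGCGCAGGCTAGAAGCAAGGACCCGATCCCCCGTGTGGCCCGTAGAGTGCAACCGCATCCATGCCAGCTCTTTCGGCAC
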