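>TVH01
GTAAGTGTTGACCGATGACGGGCAGTTGGA
>TVH02
CGAACGCTACCCGAGTCCAAGCGACGGCAC
>TVH03
AGTGTCGGCGTCGTCGACTTCATGAAAGGG
>TVH04
TGCTGTTAACCGCTTGGAGGCTTACCAGTA
>TVH05
GCACTGGACCAAATCATGTGCCTACCGTCA
>TVH06
CACGCGATATACTGAATGGCAGGCAAGCCG
>TVH07
GACGCAAAAAAAGGAAGACAAGGAGCCCCC
>TVH08
TAGGCTCGGCTACCCGGCAAGAAGGACCCT
>TVH09
GATTGAAGTCGGTTTATGGGTTCAACCATG
>TVH10
AATATACCCCTACTGAGGCATGGTTGTAAA
>TVH11
TTAAATCCGTCGGTAACACGTGTGTCTACT
>TVH12
GCCGCGAAAGTGCCAGTCCTTTAGGTCAGA
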