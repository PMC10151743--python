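>TDH01
GCGCGTTTCTACAAAAGTGG
>TDH02
ACAGAGCAAGGAATGGTCAG
>TDH03
CGCTTCACTTAGGGCCCACG
>TDH04
ACTAGTCGAGACCATCTTGA
>TDH05
CCCGAGCGAAGCACCCAGCG
>TDH06
TAGGTATAGCCTAAGATATG
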