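>TJH01
CTAACCATTCGTGT
>TJH02
CACAGCTAGAGTCG
>TJH03
ACTTGTTGGCGCGT
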