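name	rank	functionality
TVH01	1	functional
TVH02	2	functional
TVH03	3	functional
TVH04	4	functional
TVH05	5	functional
TVH06	6	functional
TVH07	7	functional
TVH08	8	functional
TVH09	9	pseudogene
TVH10	10	ORF
TVH11	11	functional
TVH12	12	functional
TDH01	1	functional
TDH02	2	functional
TDH03	3	functional
TDH04	4	functional
TDH05	5	functional
TDH06	6	functional
TJH01	1	functional
TJH02	2	functional
TJH03	3	functional
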