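marker	chromosome
BM1824	1
BM2113	2
INRA023	3
ETH10	5
ETH225	9
SPS115	15
TGLA53	16
TGLA227	18
ETH3	19
TGLA126	20
TGLA122	21
BM1818	23
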