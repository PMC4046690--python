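ancestor	rank
Homo sapiens	0
Hominidae	1
Catarrhini	2
Simiiformes	3
Primates	4
Euarchontoglires	5
Eutheria	6
Theria	7
Mammalia	8
Amniota	9
Tetrapoda	10
Euteleostomi	11
Chordata	12
Bilateria	13
Opisthokonta	14
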