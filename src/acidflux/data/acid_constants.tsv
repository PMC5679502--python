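name	pka1	pka2	pka3	carbons
citric	3.128	4.761	6.396	6
oxalic	1.252	4.266		2
gluconic	3.7			6
acetic	4.757			2
malic	3.459	5.097		4
succinic	4.207	5.636		4
lactic	3.86			3
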