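chr4	0	4500000	4p16.3
chr16	28100000	34600000	16p11.2
chr17	31800000	38100000	17q12
chr22	17900000	23300000	22q11.2
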