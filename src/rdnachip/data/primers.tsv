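name	forward	reverse	unit_kb
human rDNA 5'-ETS	CCTGCTGTTCTCTCGCGCGTCCGAG	AACGCCTGACACGCACGGCACGGAG
human UBF	GTCGGCCATGTTCATCTTCT	CTCAGACAGGTCGTTCCACA
H4	CGACGACCCATTCGAACGTCT	CTCTCCGGAATCGAACCCTGA	4
H8	AGTCGGGTTGCTTGGGAATGC	CCCTTACGGTACTTGTTGACT	8
H13	ACCTGGCGCTAAACCATTCGT	GGACAAACCCTTGTGTCGAGG	13
H18	GTTGACGTACAGGGTGGACTG	GGAAGTTGTCTTCACGCCTGA	18
H28	TCCCCAGTTTTCAGGAAGAC	AACATCAACCGGCTCTCACT	28
H42	GGTTGTCGGGCTCCATCT	CTTTCCGGAGCTCTGCCTAG	42
H42.9	CCCGGGGGAGGTATATCTTT	CCAACCTCTCCGACGACA	42.9
GAPDH	TCCACCACCCTGTTGCTGTA	ACCACAGTCCATGCCATCAC
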