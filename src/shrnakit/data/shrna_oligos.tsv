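name	gene	catalog	sequence
shPias2_48	PIAS2	TRCN0000013348	CCGGGCCATGTTATTACAGAGATTACTCGAGTAATCTCTGTAATAACATGGCTTTTT
shPias2_49	PIAS2	TRCN0000013349	CCGGCCACAATCAAATCATCGGTTTCTCGAGAAACCGATGATTTGATTGTGGTTTTT
shPias2_50	PIAS2	TRCN0000013350	CCGGGCAAGCAAGAAGAAAGTAGATCTCGAGATCTACTTTCTTCTTGCTTGCTTTTT
shPias2_51	PIAS2	TRCN0000013351	CCGGGCTGCTATTCCGCCTTCATTACTCGAGTAATGAAGGCGGAATAGCAGCTTTTT
shPias2_52	PIAS2	TRCN0000013352	CCGGCGAGTTTAGTTCAAAGCAGTACTCGAGTACTGCTTTGAACTAAACTCGTTTTT
shPias2_mu1	PIAS2_mutant	synthetic	CCGGCCACAATCAAAGAAAGTAGATCTCGAGATCTACTTTCTTTGATTGTGGTTTTT
shPias2_mu2	PIAS2_mutant	synthetic	CCGGGCAAGCAAGAATCATCGGTTTCTCGAGAAACCGATGATTCTTGCTTGCTTTTT
shPias2_mu3	PIAS2_mutant	synthetic	CCGGGCAAGCAAGAAGAAAGTGTTTCTCGAGAAACACTTTCTTCTTGCTTGCTTTTT
shPias2_mu4	PIAS2_mutant	synthetic	CCGGGCAAGCAAAAATCATCGGTTTCTCGAGAAACCGATGATTCTTGCTTGCTTTTT
shPias2_mu5	PIAS2_mutant	synthetic	CCGGGCAAGCAATAATCATCGGTTTCTCGAGAAACCGATGATTATTGCTTGCTTTTT
shPias2_mu6	PIAS2_mutant	synthetic	CCGGGCAAGCAACAATCATCGGTTTCTCGAGAAACCGATGATTGTTGCTTGCTTTTT
shPias2_mu7	PIAS2_mutant	synthetic	CCGGGCAAGCAACAAGAAAGTAGATCTCGAGATCTACTTTCTTGTTGCTTGCTTTTT
shEGFP	eGFP	RHS4459	CCGGTACAACAGCCACAACGTCTATCTCGAGATAGACGTTGTGGCTGTTGTATTTTT
shScrambled	none	Addgene_1864	CCGGCCTAAGGTTAAGTCGCCCTCGCTCGAGCGAGGGCGACTTAACCTTAGGTTTTT
shGAPDH_25828	GAPDH	TRCN0000025828	CCGGGCTCATTTCCTGGTATGACAACTCGAGTTGTCATACCAGGAAATGAGCTTTTT
shGAPDH_25830	GAPDH	TRCN0000025830	CCGGCCAGGTGGTCTCCTCTGACTTCTCGAGAAGTCAGAGGAGACCACCTGGTTTTT
shGAPDH_25836	GAPDH	TRCN0000025836	CCGGTCCGGGAAACTGTGGCGTGATCTCGAGATCACGCCACAGTTTCCCGGATTTTT
shHDAC1_4814	HDAC1	TRCN0000004814	CCGGCGTTCTTAACTTTGAACCATACTCGAGTATGGTTCAAAGTTAAGAACGTTTTT
shHDAC1_4815	HDAC1	TRCN0000004815	CCGGCGGTGGTTACACCATTCGTAACTCGAGTTACGAATGGTGTAACCACCGTTTTT
shHDAC1_4816	HDAC1	TRCN0000004816	CCGGGCCGGTCATGTCCAAAGTAATCTCGAGATTACTTTGGACATGACCGGCTTTTT
shHDAC1_4817	HDAC1	TRCN0000004817	CCGGCCGCAAGAACTCTTCCAACTTCTCGAGAAGTTGGAAGAGTTCTTGCGGTTTTT
shHDAC2_4820	HDAC2	TRCN0000004820	CCGGCCAGCGTTTGATGGACTCTTTCTCGAGAAAGAGTCCATCAAACGCTGGTTTTT
shPPP2CA_2485	PPP2CA	TRCN0000002485	CCGGGAGGGATATAACTGGTGCCATCTCGAGATGGCACCAGTTATATCCCTCTTTTT
shHDAC3_39389	Hdac3	TRCN0000039389	CCGGCGTGGCTCTCTGAAACCTTAACTCGAGTTAAGGTTTCAGAGAGCCACGTTTTT
shHDAC3_39391	Hdac3	TRCN0000039391	CCGGGTGTTGAATATGTCAAGAGTTCTCGAGAACTCTTGACATATTCAACACTTTTT
shHDAC3_39393	Hdac3	TRCN0000039393	CCGGGAGTTCTATGATGGCGACCATCTCGAGATGGTCGCCATCATAGAACTCTTTTT
shBcl2l11_9692	Bcl2l11	TRCN0000009692	CCGGGTGACAGAGAAGGTGGACAATCTCGAGATTGTCCACCTTCTCTGTCACTTTTT
shBcl2l11_9693	Bcl2l11	TRCN0000009693	CCGGTCTCAGGAGGAACCTGAAGATCTCGAGATCTTCAGGTTCCTCCTGAGATTTTT
shBcl2l11_9694	Bcl2l11	TRCN0000009694	CCGGCCCGGAGATACGGATTGCACACTCGAGTGTGCAATCCGTATCTCCGGGTTTTT
shBcl2l11_9695	Bcl2l11	TRCN0000009695	CCGGAGCTTCCATACGACAGTCTCACTCGAGTGAGACTGTCGTATGGAAGCTTTTTT
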