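# SYNTHETIC stand-in for a published bacterial rRNA-depletion oligo catalog.
# Sequences are random DNA generated with a fixed seed; only the catalog
# STRUCTURE mirrors the published design: 17 common 16S/23S oligos shared by
# all 8 organisms (8 for 16S + 9 for 23S, mean length 30 nt), 2 Gram-group
# specific 23S-end oligos per group, and 2 species-specific 5S oligos per
# organism -- 21 oligos per organism in total, each 5'-biotinylated.
# Organisms: Ec Pa Rp Cc (Gram-negative); Bs Ms Mtb Sa (Gram-positive).
name	target	scope	organisms	sequence	modification
16S_1	16S	common	all	ATTTGTATCTGGATGAAACGAGTTTC	5Biotin
16S_2	16S	common	all	TTGTGGCTTTCAAACTTCCTGTCGCTGG	5Biotin
16S_3	16S	common	all	CGTCAAATAACATTTTAATGGGGCAAGTA	5Biotin
16S_4	16S	common	all	GGTGTCGTTGTCTATCCCGACGTTCACCGG	5Biotin
16S_5	16S	common	all	GGTGCGCCGCTTAATGATAATGGCTATTGT	5Biotin
16S_6	16S	common	all	CCTACACATCTGATCTTACCTTTCCCCATAC	5Biotin
16S_7	16S	common	all	GCTTAAAGGCGTCGTAAACCGGCTCACTTATG	5Biotin
16S_8	16S	common	all	CCTGCAGTTCAGCCACGAGGAATGGATAGGGTTG	5Biotin
23S_1	23S	common	all	TACTACCACTACTTGAGGGTCCTCG	5Biotin
23S_2	23S	common	all	ATTCTGTCTCCGTTATAACAAAGTCAT	5Biotin
23S_3	23S	common	all	CTAAGGCGCTTGCGATTTTATTGGTGGCG	5Biotin
23S_4	23S	common	all	GCCAACTGTCATGGCAATGCCATGCTAAGT	5Biotin
23S_5	23S	common	all	AACCGGCGTTATTGCAATCATGGTGCATTT	5Biotin
23S_6	23S	common	all	CCCGATTCTGGTTAGTTCGACCGTTCAGGGG	5Biotin
23S_7	23S	common	all	GAACTCAAGAGTGAGTATAAGAAGAAATTAGA	5Biotin
23S_8	23S	common	all	GTAATCGATAATAGCACTTACCGTAAAGAGAAT	5Biotin
23S_9	23S	common	all	GCATTCGCACGATCCTCCCTCTTACATCATAAT	5Biotin
23S_gram_negative_1	23S	gram_negative	Ec,Pa,Rp,Cc	GTGTTTAGGTCACCGGTCAGTGTTTTAGT	5Biotin
23S_gram_negative_2	23S	gram_negative	Ec,Pa,Rp,Cc	AAGTTGCATTGTGGACTTGTCCCTGGTTACG	5Biotin
23S_gram_positive_1	23S	gram_positive	Bs,Ms,Mtb,Sa	GGACGGGTCGGACGAACATTTGTGAAACT	5Biotin
23S_gram_positive_2	23S	gram_positive	Bs,Ms,Mtb,Sa	ATTCCTGCATCGTTAGTCAACTGCGACACAG	5Biotin
5S_Ec_1	5S	species	Ec	GAGATCGCCGTAGTTAACCCCCTATTGC	5Biotin
5S_Ec_2	5S	species	Ec	ATCAACACGTCGGCAGATAAGATTTCAACAGA	5Biotin
5S_Pa_1	5S	species	Pa	ACAGTAAGCTCGCCGCCATTTCTACTGT	5Biotin
5S_Pa_2	5S	species	Pa	TCTATGTGATTCCCATTACATTTCACAGCCGT	5Biotin
5S_Rp_1	5S	species	Rp	GATACGTGGACCTATGCAGTTCGCCGGC	5Biotin
5S_Rp_2	5S	species	Rp	TGAGCCCCGCATCTAGGGGAGTCATTCTTACA	5Biotin
5S_Cc_1	5S	species	Cc	GTAGTCTTCACAGATTTACTTGAATAAC	5Biotin
5S_Cc_2	5S	species	Cc	TCCGTGGGATAGAACTAGACGATGCTAGACAA	5Biotin
5S_Bs_1	5S	species	Bs	CACGACTACCGGGCTGACCAGGAGTACT	5Biotin
5S_Bs_2	5S	species	Bs	GCCCTTGTTAGGTGTCTTAATGAAGTCTTAAC	5Biotin
5S_Ms_1	5S	species	Ms	ATTTATCTGGCACGTAGCGCCGTAGAGT	5Biotin
5S_Ms_2	5S	species	Ms	TGCGCATTCTGCGAGATTTCGTGAACGACACT	5Biotin
5S_Mtb_1	5S	species	Mtb	CCCGAGTTATGGGATGGTGTACCTTGCG	5Biotin
5S_Mtb_2	5S	species	Mtb	GTAAACGGATCCAATTAAGTGATTAATAGCTC	5Biotin
5S_Sa_1	5S	species	Sa	CTAAACAGTAAGGATCGTCCTCTGAGCG	5Biotin
5S_Sa_2	5S	species	Sa	CCATTAATGTACAGAACGCGCCATCCCGACCT	5Biotin
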