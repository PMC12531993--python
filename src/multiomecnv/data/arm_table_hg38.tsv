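chrom	p_start	p_end	q_start	q_end	length
chr1	0	121700000	125100000	248956422	248956422
chr2	0	91800000	96000000	242193529	242193529
chr3	0	87800000	94000000	198295559	198295559
chr4	0	48200000	51800000	190214555	190214555
chr5	0	46100000	50100000	181538259	181538259
chr6	0	58500000	62600000	170805979	170805979
chr7	0	58100000	62100000	159345973	159345973
chr8	0	43200000	47200000	145138636	145138636
chr9	0	42200000	45500000	138394717	138394717
chr10	0	38000000	41600000	133797422	133797422
chr11	0	51000000	55800000	135086622	135086622
chr12	0	34700000	38200000	133275309	133275309
chr13	0	16000000	18900000	114364328	114364328
chr14	0	16000000	18200000	107043718	107043718
chr15	0	17000000	20500000	101991189	101991189
chr16	0	36300000	38300000	90338345	90338345
chr17	0	22700000	27400000	83257441	83257441
chr18	0	15400000	21000000	80373285	80373285
chr19	0	24400000	28100000	58617616	58617616
chr20	0	25700000	30400000	64444167	64444167
chr21	0	10900000	13000000	46709983	46709983
chr22	0	13700000	17400000	50818468	50818468
chrX	0	58100000	63800000	156040895	156040895
chrY	0	10300000	10600000	57227415	57227415
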