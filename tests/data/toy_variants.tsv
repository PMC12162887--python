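chrom	pos	ref	alt	sample	NR	NV	GT	GQ	flag
chr1	2000	A	G	T1	100	30	0/1	60	PASS
chr1	2000	A	G	T2	100	25	0/1	60	PASS
chr1	2000	A	G	N	100	0	0/0	60	PASS
chr1	3000	A	G	T1	100	30	0/1	60	PASS
chr1	3000	A	G	T2	100	25	0/1	60	PASS
chr1	3000	A	G	N	100	0	0/0	60	PASS
chr1	4000	A	G	T1	100	30	0/1	60	PASS
chr1	4000	A	G	T2	100	25	0/1	60	PASS
chr1	4000	A	G	N	100	0	0/0	60	PASS
chr1	5000	A	G	T1	100	30	0/1	60	PASS
chr1	5000	A	G	T2	100	25	0/1	60	PASS
chr1	5000	A	G	N	100	0	0/0	60	PASS
chr2	6000	A	G	T1	100	30	0/1	60	PASS
chr2	6000	A	G	T2	100	0	0/0	60	PASS
chr2	6000	A	G	N	100	0	0/0	60	PASS
chr2	7000	A	G	T1	100	30	0/1	60	PASS
chr2	7000	A	G	T2	100	0	0/0	60	PASS
chr2	7000	A	G	N	100	0	0/0	60	PASS
chr2	8000	A	G	T1	100	0	0/0	60	PASS
chr2	8000	A	G	T2	100	28	0/1	60	PASS
chr2	8000	A	G	N	100	0	0/0	60	PASS
chr2	9000	A	G	T1	100	0	0/0	60	PASS
chr2	9000	A	G	T2	100	28	0/1	60	PASS
chr2	9000	A	G	N	100	0	0/0	60	PASS
chr3	10000	A	G	T1	100	30	0/1	60	PASS
chr3	10000	A	G	T2	100	1	0/1	60	PASS
chr3	10000	A	G	N	100	0	0/0	60	PASS
chr3	11000	A	G	T1	100	4	0/1	60	PASS
chr3	11000	A	G	T2	100	0	0/0	60	PASS
chr3	11000	A	G	N	100	0	0/0	60	PASS
chr4	12000	A	G	T1	100	30	0/1	60	badReads
chr4	12000	A	G	T2	100	0	0/0	60	badReads
chr4	12000	A	G	N	100	0	0/0	60	badReads
chr4	13000	A	G	T1	8	3	0/1	60	PASS
chr4	13000	A	G	T2	9	3	0/1	60	PASS
chr4	13000	A	G	N	100	0	0/0	60	PASS
chr4	14000	A	G	T1	100	30	0/1	60	PASS
chr4	14000	A	G	T2	100	0	0/0	60	PASS
chr4	14000	A	G	N	8	0	0/0	60	PASS
chr5	15000	A	G	T1	100	2	0/1	60	PASS
chr5	15000	A	G	T2	100	2	0/1	60	PASS
chr5	15000	A	G	N	100	0	0/0	60	PASS
chr5	16000	A	G	T1	100	30	0/1	60	PASS
chr5	16000	A	G	T2	100	0	0/0	60	PASS
chr5	16000	A	G	N	100	1	0/0	60	PASS
chr6	17000	A	G	T1	100	30	0/0	60	PASS
chr6	17000	A	G	T2	100	30	0/0	60	PASS
chr6	17000	A	G	N	100	0	0/0	60	PASS
chr6	18000	A	G	T1	100	30	0/1	60	PASS
chr6	18000	A	G	T2	10	0	0/0	60	PASS
chr6	18000	A	G	N	100	0	0/0	60	PASS
chr6	19000	A	G	T1	100	30	0/1	60	PASS
chr6	19000	A	G	T2	100	0	0/0	10	PASS
chr6	19000	A	G	N	100	0	0/0	60	PASS
chrM	20000	A	G	T1	100	30	0/1	60	PASS
chrM	20000	A	G	T2	100	0	0/0	60	PASS
chrM	20000	A	G	N	100	0	0/0	60	PASS
chr7	21000	A	G	T1	300	5	0/1	60	PASS
chr7	21000	A	G	T2	300	5	0/1	60	PASS
chr7	21000	A	G	N	100	0	0/0	60	PASS
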