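chrom	pos	ref	alt	svtype	length	1	2	3	4	5	6	7	8
chr1	10000	A	AG	INS	1	1	2	0	1	1	2	0	1
chr2	10000	A	AAGA	INS	3	0	1	0	1	0	2	0	2
chr2	20000	ATAG	A	DEL	3	0	1	0	1	1	2	0	2
chr2	30000	A	AGTT	INS	3	0	1	0	1	0	2	1	2
chr2	40000	A	AT	INS	1	0	1	0	1	1	2	1	2
chr2	50000	AA	A	DEL	1	0	2	0	1	0	2	1	2
chr2	60000	A	AACTTAAGTATATAACCTTAAC	INS	21	0	1	0	1	0	2	0	2
chr2	70000	ACC	A	DEL	2	0	1	0	1	1	2	1	2
chr2	80000	AC	A	DEL	1	0	1	0	1	0	2	1	2
chr2	90000	A	AACAC	INS	4	1	0	2	1	2	0	2	0
chr3	10000	AAA	A	DEL	2	2	0	1	0	2	1	1	0
chr3	20000	A	AATTCTGGGG	INS	9	2	0	1	0	2	0	1	0
chr4	10000	A	AGGC	INS	3	2	0	2	0	2	1	2	1
chr4	20000	A	AC	INS	1	2	0	2	0	2	1	2	1
chr5	10000	A	AGG	INS	2	2	0	2	0	2	0	2	0
chr6	10000	AT	A	DEL	1	0	1	0	1	0	1	0	1
chr7	10000	A	AT	INS	1	2	0	1	0	2	1	2	1
chr7	20000	AAT	A	DEL	2	1	0	1	0	2	1	2	1
chr7	30000	AA	A	DEL	1	1	0	1	0	2	1	2	1
chr7	40000	AAAAA	A	DEL	4	0	1	1	2	0	1	0	2
chr8	10000	ACATTT	A	DEL	5	0	2	0	2	0	1	1	2
chr9	10000	ATTTTTG	A	DEL	6	1	0	1	0	1	0	1	0
chr10	10000	A	AAT	INS	2	0	2	0	2	0	2	0	1
chr11	10000	A	AT	INS	1	0	2	0	1	0	2	0	1
chr11	20000	A	AG	INS	1	0	2	0	1	0	2	0	1
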