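##fileformat=VCFv4.2
##contig=<ID=g1,length=2000>
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	S01	S02	S03	S04	S05	S06	S07	S08	S09	S10
g1	100	.	AT	A	.	PASS	MQ=59	GT:DP:GQ	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/1:30:50	0/1:30:50	0/1:30:50	0/1:30:50	1/1:30:50	1/1:30:50
g1	200	.	A	C,G	.	PASS	MQ=59	GT:DP:GQ	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/1:30:50	0/2:30:50
g1	300	.	A	C	.	PASS	MQ=59	GT:DP:GQ	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50
g1	400	.	A	C	.	PASS	MQ=59	GT:DP:GQ	./.:30:50	./.:30:50	0/1:30:50	0/1:30:50	0/1:30:50	0/0:30:50	1/1:30:50	0/0:30:50	0/0:30:50	0/0:30:50
g1	500	.	A	C	.	PASS	MQ=59	GT:DP:GQ	0/0:30:10	0/1:30:10	0/1:30:10	0/0:30:50	1/1:30:50	0/0:30:50	0/1:30:50	0/0:30:50	0/0:30:50	0/1:30:50
g1	600	.	A	C	.	PASS	MQ=30	GT:DP:GQ	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/1:30:50	0/1:30:50	0/1:30:50	0/1:30:50	1/1:30:50	1/1:30:50
g1	700	.	A	C	.	PASS	MQ=59	GT:DP:GQ	0/0:2:50	0/0:2:50	0/0:2:50	0/0:2:50	0/1:2:50	0/1:2:50	0/1:2:50	0/1:2:50	1/1:2:50	1/1:2:50
g1	800	.	A	C	.	PASS	MQ=59	GT:DP:GQ	0/1:30:50	0/1:30:50	0/1:30:50	0/1:30:50	0/1:30:50	0/1:30:50	0/1:30:50	0/0:30:50	1/1:30:50	0/0:30:50
g1	900	.	A	C	.	PASS	MQ=59	GT:DP:GQ	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/1:30:50	0/1:30:50	0/1:30:50	0/1:30:50	1/1:30:50	1/1:30:50
g1	1000	.	A	C	.	PASS	MQ=59	GT:DP:GQ	0/1:30:50	0/1:30:50	0/1:30:50	0/1:30:50	0/1:30:50	0/0:30:50	0/0:30:50	0/0:30:50	1/1:30:50	1/1:30:50
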