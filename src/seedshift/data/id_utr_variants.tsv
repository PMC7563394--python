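chr	pos	ref	alt	VEP_Ensembl_Gene_Name
1	100541492	T	G	GPR88
3	13818428	G	T	WNT7A
3	13818646	T	A	WNT7A
3	13818646	T	C	WNT7A
3	13818646	T	G	WNT7A
3	13818647	A	C	WNT7A
3	13818647	A	G	WNT7A
3	13818647	A	T	WNT7A
3	13818648	T	A	WNT7A
3	13818648	T	C	WNT7A
3	13818648	T	G	WNT7A
3	13818649	T	A	WNT7A
3	13818649	T	C	WNT7A
3	13818649	T	G	WNT7A
3	13818650	G	A	WNT7A
3	13818650	G	C	WNT7A
3	13818650	G	T	WNT7A
7	92605125	T	A	CDK6
7	92607925	A	G	CDK6
7	92607993	A	C	CDK6
7	92607993	A	G	CDK6
7	92607993	A	T	CDK6
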