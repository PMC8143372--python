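patient	pre_mutation	pre_rrscna	pre_tf	post_mutation	post_rrscna	post_tf
Case 1	L858R, T790M	No rrSCNAs	4.5%	L858R, T790M	MET	7.4%
Case 2	del19, T790M	No rrSCNAs	3.0%	del19, T790M	No rrSCNAs	4.1%
Case 3	T790M	No rrSCNAs	4.5%	-	No rrSCNAs	4.5%
Case 4	del19, T790M	MDM2	7.2%	del19, T790M	No rrSCNAs	5.0%
Case 5	T790M	No rrSCNAs	5.0%	del19, C797S	No rrSCNAs	3.9%
Case 6	del19, T790M	No rrSCNAs	4.1%	-	No rrSCNAs	3.9%
Case 7	T790M	No rrSCNAs	3.6%	del19	No rrSCNAs	5.0%
Case 8	L858R, T790M	CDK4, MDM2	7.6%	L858R, T790M	CDK4, MDM2, ERBB2, PIK3CA	10.1%
Case 9	T790M	No rrSCNAs	<3.0%	-	No rrSCNAs	3.4%
Case 10	del19, T790M	EGFR, CDK4, MDM2	19.4%	del19, T790M, C797S	CDK4, MDM2	3.4%
Case 11	T790M	EGFR	22.5%	del19	EGFR	6.7%
Case 12	del19, T790M	No rrSCNAs	5.6%	del19, T790M, C797S	EGFR, CDK4	5.9%
Case 13	del19, T790M	No rrSCNAs	5.3%	del19	No rrSCNAs	10.2%
Case 14	del19, T790M	No rrSCNAs	4.0%	del19, T790M, C797S	No rrSCNAs	3.3%
Case 15	T790M	No rrSCNAs	3.1%	-	No rrSCNAs	3.3%
Case 16	L858R, T790M	ERBB2, CDKN2A	42.4%	L858R, T790M	ERBB2	23.7%
Case 17	L858R, T790M	No rrSCNAs	4.8%	L858R	No rrSCNAs	4.1%
Case 18	del19, T790M	No rrSCNAs	4.9%	-	No rrSCNAs	4.8%
Case 19	T790M	No rrSCNAs	8.7%	-	No rrSCNAs	9.9%
Case 20	del19, T790M	No rrSCNAs	4.9%	del19	No rrSCNAs	4.7%
Case 21	del19, T790M	No rrSCNAs	5.1%	del19	No rrSCNAs	4.9%
Case 22	del19, T790M	No rrSCNAs	3.7%	-	No rrSCNAs	3.2%
Case 23	del19, T790M	EGFR	21.0%	del19, T790M, C797S	EGFR	15.3%
Case 24	T790M	No rrSCNAs	3.3%	-	No rrSCNAs	4.5%
Case 25	del19, T790M	No rrSCNAs	<3.0%	del19, T790M	No rrSCNAs	15.5%
Case 26	del19, T790M	AKT2, RB1	23.8%	T790M	AKT2, RB1	42.6%
Case 27	L858R, T790M	No rrSCNAs	3.2%	L858R, T790M, C797S	No rrSCNAs	3.7%
Case 28	L858R, T790M	No rrSCNAs	7.5%	L858R, T790M, C797S	No rrSCNAs	4.4%
Case 29	L858R, T790M	EGFR, CDK6	14.6%	L858R, T790M	No rrSCNAs	5.3%
Case 30	del19, T790M	EGFR	6.9%	del19	No rrSCNAs	30.8%
Case 31	L858R, T790M	No rrSCNAs	3.0%	L858R	No rrSCNAs	4.1%
Case 32	L861Q, T790M	EGFR	7.0%	L861Q	EGFR, ERBB2	7.0%
Case 33	del19, T790M	No rrSCNAs	6.2%	del19, T790M, C797S	No rrSCNAs	4.3%
Case 34	L858R, T790M	No rrSCNAs	3.9%	-	No rrSCNAs	4.0%
Case 35	T790M	No rrSCNAs	5.7%	-	No rrSCNAs	4.2%
Case 36	del19, T790M	No rrSCNAs	5.9%	-	No rrSCNAs	4.0%
Case 37	del19, T790M	No rrSCNAs	3.9%	del19	No rrSCNAs	7.8%
Case 38	del19, T790M	No rrSCNAs	5.1%	del19	No rrSCNAs	<3.0%
Case 39	L858R, T790M	No rrSCNAs	3.8%	L858R	No rrSCNAs	<3.0%
Case 40	L861Q, T790M	No rrSCNAs	7.9%	L861Q	EGFR	4.5%
Case 41	del19, T790M	No rrSCNAs	4.1%	del19, T790M	No rrSCNAs	4.5%
Case 42	del19, T790M	No rrSCNAs	<3.0%	-	CDKN2A	8.3%
Case 43	del19, T790M	No rrSCNAs	5.1%	del19, T790M	No rrSCNAs	5.0%
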