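patient	activating_copies_per_ml	t790m_copies_per_ml	tf	scna	excluded
Case 1	6.7	6.9	4.5%	Yes	no
Case 2	73.1	50.4	3.0%	No	yes
Case 3	0	5.2	4.5%	No	yes
Case 4	179.2	86.0	7.2%	Yes	no
Case 5	0	2.9	5.0%	No	no
Case 6	173.9	10.1	4.1%	No	yes
Case 7	0	6.4	3.6%	No	yes
Case 8	166.3	38.1	7.6%	Yes	no
Case 9	0	1.6	<3.0%	No	yes
Case 10	33559.8	38092.5	19.4%	Yes	no
Case 11	0	2.1	22.5%	Yes	no
Case 12	20.9	14.5	5.6%	No	no
Case 13	5.1	2.5	5.3%	Yes	no
Case 14	710.1	124.6	4.0%	Yes	no
Case 15	0	2.3	3.1%	Yes	no
Case 16	21119.3	7.9	42.4%	Yes	no
Case 17	7.6	52.0	4.8%	No	yes
Case 18	2.7	2.3	4.9%	Yes	no
Case 19	0	7.9	8.7%	No	no
Case 20	122.6	1.9	4.9%	No	yes
Case 21	8.4	5.2	5.1%	No	no
Case 22	763.6	10.2	3.7%	No	yes
Case 23	5010.5	3354.0	21.0%	Yes	no
Case 24	0	1.9	3.3%	No	yes
Case 25	156.8	52.4	<3.0%	Yes	no
Case 26	1571.9	254.5	23.8%	Yes	no
Case 27	341.6	111.9	3.2%	No	yes
Case 28	966.8	261.2	7.5%	No	no
Case 29	3891.9	444.3	14.6%	Yes	no
Case 30	4217.9	649.8	6.9%	Yes	no
Case 31	125.3	17.0	3.0%	Yes	no
Case 32	12660.3	1.8	7.0%	Yes	no
Case 33	201.6	39.2	6.2%	Yes	no
Case 34	5.5	1.8	3.9%	No	yes
Case 35	0	75.8	5.7%	No	no
Case 36	164.1	52.0	5.9%	No	no
Case 37	29.3	9.6	3.9%	Yes	no
Case 38	373.1	91.1	5.1%	No	no
Case 39	38.0	9.0	3.8%	Yes	no
Case 40	8373.2	6.0	7.9%	No	no
Case 41	231.1	93.8	4.1%	Yes	no
Case 42	1.1	1.9	<3.0%	No	yes
Case 43	1540.7	379.8	5.1%	No	no
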