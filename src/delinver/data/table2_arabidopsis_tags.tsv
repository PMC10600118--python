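locus	guide_pair	deletion_size_kb	n_transgenic	n_deletion	printed_deletion_freq_pct	n_delinver	printed_delinver_freq_pct	printed_ratio_pct
AtMC7/6/5/4	MC7+MC4	8.2	90	3	3.3	1	1.1	33.3
AtCHI1/2/3/4/5/6	CHI1+CHI6	18.7	157	30	19.1	17	10.8	56.7
AT5G45240/AtRPS4/AtRRS1	L1+R1	18.4	147	113	76.9	83	56.5	73.5
AT5G45240/AtRPS4/AtRRS1	L1+R2	18.3	8	5	62.5	2	25.0	40.0
AT5G45240/AtRPS4/AtRRS1	L1+R3	18.2	32	0	0	0	0	0
AT5G45240/AtRPS4/AtRRS1	L1+R4	18.2	383	270	70.5	203	53.0	75.2
AT5G45240/AtRPS4/AtRRS1	L1+R5	18.2	10	2	20.0	1	10.0	50.0
AT5G45240/AtRPS4/AtRRS1	L1+R6	18.2	18	14	77.8	10	55.6	71.4
AT5G45240/AtRPS4/AtRRS1	L1+R7	18.1	218	132	60.6	90	41.3	68.2
AT5G45240/AtRPS4/AtRRS1	L1+R8	17.9	101	6	5.9	0	0	0
AT5G45240/AtRPS4/AtRRS1	L2+R9	14.3	24	15	62.5	12	50.0	80.0
AT5G45240/AtRPS4/AtRRS1	L2+R10	11.2	98	39	39.8	20	20.4	51.3
AT5G45240/AtRPS4/AtRRS1	L3+R9	11	46	13	28.3	2	4.3	15.4
AT5G45240/AtRPS4/AtRRS1	L3+R10	8	208	24	11.5	6	2.9	25.0
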