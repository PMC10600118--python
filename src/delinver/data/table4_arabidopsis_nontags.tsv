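locus	guide_pair	deletion_size_kb	n_transgenic	n_deletion	printed_deletion_freq_pct	n_delinver	printed_delinver_freq_pct	printed_ratio_pct
AtRRS1/AT5G45275/AT5G45276/AT5G45277/AT5G45280/AT5G45290	L4+R3	18.2	19	1	5.3	0	0	0
AtRRS1/AT5G45275/AT5G45276/AT5G45277/AT5G45280/AT5G45290	L5+R3	18.2	104	39	37.5	21	20.2	53.8
AtRRS1/AT5G45275/AT5G45276/AT5G45277/AT5G45280/AT5G45290	L4+R4	18.2	92	14	15.2	6	6.5	42.9
AtRRS1/AT5G45275/AT5G45276/AT5G45277/AT5G45280/AT5G45290	L5+R4	18.2	105	27	25.7	19	18.1	70.4
AT5G47980/AtTHAD/AtTHAH/AtTHAS	L1+R1	32	80	45	56.3	30	37.5	66.7
AT5G47980/AtTHAD/AtTHAH/AtTHAS	L2+R2	32.3	95	7	7.4	3	3.2	42.9
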