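locus	guide_pair	deletion_size_kb	n_transgenic	n_deletion	printed_deletion_freq_pct	n_delinver	printed_delinver_freq_pct	printed_ratio_pct
OsPEPR1/LOC_Os08g34630/OsPEPR2	PEPR1.1+PEPR1.2+PEPR2.1+PEPR2.2	7.2~12.2	300	49	16.3	7	2.3	14.3
OsPROPEP2/6/5/3/7/4	PEP2+PEP3	22.1	303	81	26.7	64	21.1	79.0
OsPROPEP2/6/5/3/7/4	PEP2+PEP7	25.5	303	13	4.3	1	0.3	7.7
OsPROPEP2/6/5/3/7/4	PEP2+PEP4	32.3	303	32	10.6	4	1.3	12.5
OsPROPEP2/6/5/3/7/4	PEP6+PEP4	16.9	303	12	3.9	0	0	0
OsPROPEP2/6/5/3/7/4	PEP5+PEP4	14.3	303	10	3.3	2	0.7	20.0
OsPROPEP2/6/5/3/7/4	PEP2+PEP6	15.4	303	20	6.6	0	0	0
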