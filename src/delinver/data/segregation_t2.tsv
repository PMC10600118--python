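parent_class	offspring_class	count
DV	DV	59
DV	DD	20
DV	VV	17
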