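# source_iri	target_iri	relation	confidence
fma#Cardinal_cell_part	nci#Cell_Part	=	0.9
fma#Surface_of_cell	nci#Cell_Surface	=	0.8
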