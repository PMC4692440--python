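# source_iri	target_iri	relation	confidence
fig1#C	fig1#J	=	0.8
fig1#G	fig1#I	=	0.6
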