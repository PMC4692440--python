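# Toy "green" ontology of the two-ontology worked example (reconstructed).
CLASS fig1#I
CLASS fig1#J
SUB fig1#J fig1#I
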