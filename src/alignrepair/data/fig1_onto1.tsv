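# Toy "blue" ontology of the two-ontology worked example (reconstructed
# edge list satisfying every stated membership fact).
CLASS fig1#C
CLASS fig1#D
CLASS fig1#E
CLASS fig1#F
CLASS fig1#G
SUB fig1#D fig1#C
SUB fig1#D fig1#E
SUB fig1#F fig1#C
SUB fig1#F fig1#E
DIS fig1#E fig1#G
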