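# NCI-side excerpt: cell surface under cell part (reconstructed desk-scale
# stand-in, not an NCI Thesaurus export).
CLASS nci#Cell_Part
CLASS nci#Cell_Surface
SUB nci#Cell_Surface nci#Cell_Part
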