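# FMA-side excerpt around the anatomical-surface / cardinal-cell-part
# disjointness (reconstructed desk-scale stand-in, not an FMA export).
CLASS fma#Anatomical_surface
CLASS fma#Cardinal_cell_part
CLASS fma#Surface_of_cell
SUB fma#Surface_of_cell fma#Anatomical_surface
DIS fma#Anatomical_surface fma#Cardinal_cell_part
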