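# Synthetic coarse-grained E. coli cytoplasm composition (hard-sphere radii).
# This is a stand-in composition in the spirit of coarse-grained cytoplasm
# models: ~9 species spanning 0.8-13 nm, including a GFP-like species
# (2.4 nm) and a ribosome-like species (13 nm).  Counts are relative;
# build_cytoplasm rescales the box so the macromolecules reach the requested
# occupied volume fraction.  Replace with a measured table for fidelity.
label,radius_nm,count
ribosome,13.0,6
large_complex,8.5,4
polymerase_like,6.5,10
medium_protein,4.5,30
enzyme_like,3.4,60
gfp_like,2.4,120
small_protein,1.8,200
peptide,1.2,120
small_solute,0.8,40
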