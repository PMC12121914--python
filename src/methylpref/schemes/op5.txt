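# Op5 reduced amino-acid alphabet (5 groups).
# RECONSTRUCTED scheme: only the 11-group partition of the protein-block
# clustering series is printed in the primary reference; this 5-group variant
# is a nested coarsening of Op11 along physicochemical lines (aliphatic/
# aromatic hydrophobics merged; charged/amide merged; small/polar merged).
# Used for grid-search plumbing only; headline results use Op11.
G: G
I: IVFYWALM
E: EQRK
P: P
N: NDHSTC
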