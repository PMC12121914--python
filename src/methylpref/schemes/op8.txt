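# Op8 reduced amino-acid alphabet (8 groups).
# RECONSTRUCTED scheme: nested coarsening of the printed Op11 partition
# (beta-branched + aromatic hydrophobics merged; A merged with L/M;
# H/S merged with T).  Grid-search plumbing only; headline results use Op11.
G: G
I: IVFYW
A: ALM
E: EQRK
P: P
N: ND
H: HST
C: C
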