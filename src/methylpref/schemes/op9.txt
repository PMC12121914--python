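# Op9 reduced amino-acid alphabet (9 groups).
# RECONSTRUCTED scheme: nested coarsening of the printed Op11 partition
# (A merged with L/M; T merged with H/S).  Grid-search plumbing only;
# headline results use Op11.
G: G
I: IV
F: FYW
A: ALM
E: EQRK
P: P
N: ND
H: HST
C: C
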