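# Op13 reduced amino-acid alphabet (13 groups).
# RECONSTRUCTED scheme: nested refinement of the printed Op11 partition
# (I/V split; L/M split).  Grid-search plumbing only; headline results
# use Op11.
G: G
I: I
V: V
F: FYW
A: A
L: L
M: M
E: EQRK
P: P
N: ND
H: HS
T: T
C: C
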