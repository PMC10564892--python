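# Per-position amino-acid alphabets for exhaustive central-sequence enumeration
# (nonamer positions P3..P8; P1/P2/P9 are held fixed by the caller).
# SYNTHETIC TRANSCRIPTION STAND-IN: the published per-position similarity-matrix
# cutoff defines the real sets; only their sizes (8-11 residues plus proline,
# product 784,080) are fixed by the main text, and those sizes are reproduced
# here.  Residue identities below are a plausible example; override with your
# own TSV via load_alphabets(path).
# position	amino_acids
3	A,D,E,F,G,I,L,N,P,S,W
4	A,D,E,G,K,N,P,S,T
5	A,D,F,G,I,L,N,P,V,Y
6	A,E,G,I,L,N,P,S,T,V,W
7	A,F,H,I,L,P,S,T,V
8	A,E,K,L,P,S,T,V
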