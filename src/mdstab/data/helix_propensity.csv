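amino_acid,penalty_kj_mol
A,0.00
L,0.88
R,0.88
M,1.00
K,1.09
Q,1.63
E,1.67
I,1.72
W,2.05
S,2.09
Y,2.22
F,2.26
H,2.55
V,2.55
N,2.72
T,2.76
C,2.85
D,2.89
G,4.18
P,13.22
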