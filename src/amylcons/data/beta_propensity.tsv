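# Chou-Fasman beta-strand conformational propensities (P-beta), used for
# sliding-average beta-strand contiguity scoring.
# Transcribed from Chou & Fasman, Biochemistry 13:222-245 (1974).
# residue	value
A	0.83
C	1.19
D	0.54
E	0.37
F	1.38
G	0.75
H	0.87
I	1.60
K	0.74
L	1.30
M	1.05
N	0.89
P	0.55
Q	1.10
R	0.93
S	0.75
T	1.19
V	1.70
W	1.37
Y	1.47
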