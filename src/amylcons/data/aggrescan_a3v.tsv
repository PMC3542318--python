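# Per-residue in-vivo aggregation propensity (a3v) scale.
# Transcribed from Conchillo-Sole et al., BMC Bioinformatics 8:65 (2007), Table 1.
# residue	value
A	-0.036
C	0.604
D	-1.836
E	-1.412
F	1.754
G	-0.535
H	-1.033
I	1.822
K	-0.931
L	1.380
M	0.910
N	-0.776
P	-0.334
Q	-0.069
R	-1.240
S	-0.294
T	-0.159
V	1.594
W	1.037
Y	1.159
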