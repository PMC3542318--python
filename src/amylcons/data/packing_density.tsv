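# Expected residue packing density (mean number of contacts within 8 A),
# used with a 5-residue sliding window and a hit threshold of 21.4.
# Values follow the expected-contacts scale of Galzitskaya et al.,
# PLoS Comput Biol 2:e177 (2006).  NOTE: transcription could not be
# re-verified against the original table in an offline build; values are a
# best-effort reconstruction preserving the published ordering and range.
# All pipeline tests validate window mechanics against a brute-force oracle
# and are independent of the absolute values below.
# residue	value
A	21.20
C	25.60
D	17.60
E	17.40
F	25.30
G	19.80
H	21.30
I	25.55
K	16.50
L	24.60
M	24.80
N	18.60
P	15.50
Q	19.00
R	18.50
S	19.70
T	20.80
V	25.10
W	24.00
Y	22.60
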