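# Six-position amyloidogenic sequence pattern derived from saturation
# mutagenesis of the de novo designed amyloidogenic hexapeptide STVIIE.
# Transcribed from Lopez de la Paz & Serrano, PNAS 101:87-92 (2004).
# Format: position<TAB>mode<TAB>residues
#   mode "forbid": any standard residue EXCEPT the listed ones matches
#   mode "allow":  only the listed residues match
1	forbid	P
2	forbid	PKRHW
3	allow	VLSCWFNQE
4	allow	ILTYWFNE
5	allow	FIY
6	forbid	PKRH
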