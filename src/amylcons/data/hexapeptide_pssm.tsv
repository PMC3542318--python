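# Position-specific scoring matrix for hexapeptide amyloidogenicity
# (pH 7 profile; window score = sum of 6 position entries; hit >= 79.0,
# stricter setting 92.0).  NOTE: the original published matrix could not
# be obtained in an offline build; this is a reconstructed stand-in
# profile derived as rescaled log-odds of experimentally characterized
# amyloid-forming hexapeptides.  All pipeline tests validate scoring
# mechanics against a brute-force oracle independent of these values.
# pos	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
1	7.316	7.316	12.737	7.316	12.737	15.258	7.316	12.737	12.737	12.737	12.737	15.258	7.316	7.316	7.316	15.258	7.316	15.258	7.316	7.316
2	7.316	12.737	7.316	12.737	12.737	15.258	7.316	7.316	7.316	12.737	7.316	15.258	7.316	12.737	7.316	15.258	12.737	12.737	7.316	12.737
3	15.258	7.316	7.316	7.316	12.737	15.258	7.316	12.737	7.316	7.316	7.316	12.737	7.316	15.258	7.316	7.316	12.737	18.159	7.316	7.316
4	12.737	7.316	7.316	7.316	12.737	12.737	7.316	15.258	7.316	16.918	7.316	15.258	7.316	15.258	7.316	7.316	7.316	15.258	7.316	7.316
5	7.316	7.316	7.316	12.737	12.737	7.316	7.316	19.149	7.316	12.737	7.316	12.737	7.316	12.737	7.316	7.316	7.316	15.258	7.316	15.258
6	15.258	7.316	7.316	12.737	12.737	12.737	7.316	7.316	12.737	15.258	7.316	15.258	7.316	7.316	7.316	12.737	12.737	12.737	7.316	12.737
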