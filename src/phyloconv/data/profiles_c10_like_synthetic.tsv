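# Synthetic amino acid profile library: 10 fixed, data-independent
# propensity profiles built from physicochemical residue groupings
# (0.85 probability mass uniform within the group, 0.15 spread over
# all 20 residues). A constructed stand-in playing the role of a
# CAT-C10-style category set; NOT the published CAT-C10 estimates.
profile	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
aliphatic	0.177500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.177500	0.177500	0.007500	0.177500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.177500
aromatic	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.290833	0.007500	0.007500	0.007500	0.290833	0.290833	0.007500
hydroxyl	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.432500	0.432500	0.007500	0.007500	0.007500
acidic	0.007500	0.007500	0.007500	0.432500	0.007500	0.007500	0.432500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500
basic	0.007500	0.432500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.432500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500
amide	0.007500	0.007500	0.432500	0.007500	0.007500	0.432500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500
small	0.290833	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.290833	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.290833	0.007500	0.007500	0.007500	0.007500
sulfur	0.007500	0.007500	0.007500	0.007500	0.432500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.432500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500
imidazole_proline	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.007500	0.432500	0.007500	0.007500	0.007500	0.007500	0.007500	0.432500	0.007500	0.007500	0.007500	0.007500	0.007500
broad	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000
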