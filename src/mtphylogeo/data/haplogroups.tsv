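# Bundled haplogroup-definition tree (fixture).
# Columns: Name, Parent, Motif (space-separated tokens; "@" = back mutation),
# Ancestry (optional macro-ancestry label).
# Motifs marked "placeholder" below are stand-ins chosen for testability, not
# published defining motifs; the clades whose printed defining variants are
# public carry those exact variants (M54a, M55b, M84b).
Name	Parent	Motif	Ancestry
root
M	root	489 10398 10400 14783 15043 16223
N	root	8701 10873 15301
R	N	16076
A	N	663 1736 4824 16290 16319	EastEurasian
B	R	8281-8289d 16189	EastEurasian
D4	M	3010 4883 5178A 8414 14668 16362	EastEurasian
M24	M	8793 16270	Other
M45	M	3921 16079	SouthAsian
M5	M	1888 16129	SouthAsian
M54	M	8865 16357	Other
M54a	M54	12414 16189	Other
M55	M	5301 9254 16304	Other
M55b	M55	373 1047 1719 5564 7972 16172 @10398	Other
M84	M	4561 16201	Other
M84a	M84	6620 16234	Other
M84b	M84	150 152 279 6260 16311	Other
M90	M	7142 16253	Other
M91	M	11150 16166	Other
# placeholder motifs: N, R, M24, M45, M5, M54, M55, M84, M84a, M90, M91
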