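# curated fixture set: substituted rings (ortho/meta/para chloro, bromo,
# hydroxyl motifs), salts, charged and multi-fragment species
CCO	ethanol	1
c1ccccc1	benzene	0
Cc1ccccc1	toluene	0
Oc1ccccc1	phenol	1
Clc1ccccc1	chlorobenzene	0
Brc1ccccc1	bromobenzene	0
Oc1ccccc1Cl	2-chlorophenol	1
Oc1cccc(Cl)c1	3-chlorophenol	1
Oc1ccc(Cl)cc1	4-chlorophenol	0
Oc1ccccc1Br	2-bromophenol	1
Oc1cccc(Br)c1	3-bromophenol	1
CC(=O)Oc1ccccc1C(=O)O	aspirin	0
Cn1cnc2c1c(=O)n(C)c(=O)n2C	caffeine	0
CC(=O)[O-]	acetate	0
C[N+](C)(C)C.[Cl-]	tetramethylammonium-chloride	0
CCN(CC)CC	triethylamine	0
OCCO	ethylene-glycol	0
c1ccc2ccccc2c1	naphthalene	1
CC(N)C(=O)O	alanine	0
CCO.O.[Na+].[Cl-]	ethanol-hydrate-salt	1
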