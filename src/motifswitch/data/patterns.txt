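# Default domain-binding motif pattern library.
# One pattern per line: family <TAB> name <TAB> pattern <TAB> phospho_index
# phospho_index is the 0-based position whose phosphorylation the family
# requires for binding (SH2, WW-classIV) or whose phosphorylation blocks
# binding (class I WW tyrosine); '-' if not applicable.
# Syntax: '.'/'x' = any residue, [ABC] = allowed set.
# ELM-style defaults; replaceable via --patterns.
SH2	Grb2	Y.N.	0
SH2	Stat5	Y[VLTFIC]	0
SH2	Src	Y[DE].[ILVM]	0
SH2	PI3K	Y..M	0
SH3	PxxP	P..P	-
SH3	classI	[RK]..P..P	-
SH3	classII	P..P.[KR]	-
SH3	RxxK	R..K	-
SH3	PxxDY	P..DY	4
WW-classI	PPxY	PP.Y	3
WW-classIV	pSP	[ST]P	0
PDZ	classI	.[ST].[VIL]	-
PDZ	classII	.[VILF].[VIL]	-
PDZ	classIII	.[ED].[VIL]	-
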