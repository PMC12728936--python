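# Bundled fixture torsion library.
# Columns: rank	class	smarts	pattern_id
# Ranks 1-3 are motif SMARTS as published for conjugated diene, ortho-fluoro
# benzamide and aryl alkyl ether central bonds; ranks 4-10 are SYNTHETIC
# filler patterns written for this package so that every hierarchy class is
# populated.  The G-G wildcard acts as the general fallback.
1	C-C	[CX3H0:1]=[CX3H0:2]!@;-[CX3:3]=[CX3:4]	diene_cc
2	C-C	[$([cH0]F):1][c:2]([cH1])!@;-[CX3:3]([NX3H1])=[O:4]	fbenzamide_cc
3	C-O	[cH1:1][c:2](cO)!@;-[O:3][C:4]	arylether_co
4	C-C	[c:1][c:2]!@;-[CX4:3][C:4]	benzylic_cc_synthetic
5	C-O	[C:1][CX4:2]!@;-[OX2:3][C:4]	alkylether_co_synthetic
6	N-C	[O:1]=[C:2]!@;-[NX3:3][C:4]	amide_nc_synthetic
7	C-S	[C:1][CX4:2]!@;-[SX2:3][C:4]	thioether_cs_synthetic
8	S-N	[C:1][SX4:2]!@;-[NX3:3][C:4]	sulfonamide_sn_synthetic
9	S-S	[C:1][SX2:2]!@;-[SX2:3][C:4]	disulfide_ss_synthetic
10	G-G	[*:1][*:2]!@;-[*:3][*:4]	general_gg
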