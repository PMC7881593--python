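# Lung-cancer copy-number loci, GRCh38 (approximate gene spans; editable).
# Columns: chrom, start, end, gene. Assembly: GRCh38.
chr7	55019017	55211628	EGFR
chr5	38938021	39074510	RICTOR
chr8	127735434	127742951	MYC
chr3	179148114	179240093	PIK3CA
chr12	25205246	25250936	KRAS
chr7	116672196	116798386	MET
chr8	38411138	38468834	FGFR1
chr11	69641156	69654474	CCND1
chr9	21967752	21995043	CDKN2A
chr10	87863625	87971930	PTEN
chr17	39687914	39730426	ERBB2
chr3	181711925	181714436	SOX2
chr5	1253167	1295068	TERT
chr12	68808172	68850686	MDM2
chr12	57747727	57756013	CDK4
chr14	36516392	36521149	NKX2-1
chr19	1205778	1228431	STK11
chr13	48303748	48481890	RB1
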