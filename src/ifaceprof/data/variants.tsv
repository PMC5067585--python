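# Built-in STAT5A variant table (STAT5A numbering). Somatic disease mutations
# carry cohort carrier/total counts and the frequency as printed in the source
# reports (printed_pct at printed_decimals precision); engineered structure-
# function mutants have no cohort. flag=count_mismatch marks rows whose printed
# percentage is inconsistent with the stored counts.
# Columns: position wt mut cohort_label carriers total printed_pct printed_decimals flag note
position	wt	mut	cohort_label	carriers	total	printed_pct	printed_decimals	flag	note
628	T	S	T-PLL	3	50	6.0	1		beta-sheet C; pY-binding pocket
642	N	H	NK-TCL	7	21	33.3	1		betaD5; pY-binding pocket
642	N	H	gd-TCL	14	94	14.9	1		betaD5; pY-binding pocket
642	N	H	T-PLL	11	50	22.0	1		betaD5; pY-binding pocket
642	N	H	T-ALL	5	68	7.4	1		betaD5; pY-binding pocket
642	N	H	pediatric-T-ALL	19	301	6.3	1		betaD5; pY-binding pocket
642	N	H	LGLL	4	211	1.9	1		betaD5; pY-binding pocket
665	Y	F	T-PLL	3	50	6.0	1		hydrophobic F706-acceptor interface
665	Y	F	NK/gd-TCL	2	94	2.1	1		hydrophobic F706-acceptor interface
665	Y	F	T-ALL	1	68	1.5	1		hydrophobic F706-acceptor interface
665	Y	F	LGLL	2	211	1	0		hydrophobic F706-acceptor interface
699	I	L	NK/gd-TCL	1	94	2.0	1	count_mismatch	PTM pY+5; I704L in STAT5B numbering
699	I	L	T-ALL	1	68	2.0	1	count_mismatch	PTM pY+5; I704L in STAT5B numbering
701	Q	L	T-PLL	1	50	2.0	1		PTM pY+7; Q706L in STAT5B numbering
618	R	Q	-	-	-	-	-		engineered; invariant betaB arginine, non-functional control
633	F	A	-	-	-	-	-		engineered; hydrophobic F706-acceptor interface
641	W	A	-	-	-	-	-		engineered; hydrophobic F706-acceptor interface
665	Y	A	-	-	-	-	-		engineered; hydrophobic F706-acceptor interface
706	F	A	-	-	-	-	-		engineered; intramolecular PTM anchor
706	F	G	-	-	-	-	-		engineered; intramolecular PTM anchor
710	S	F	-	-	-	-	-		nTAD position adjacent to the PTM
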