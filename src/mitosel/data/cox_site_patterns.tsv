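# Curated per-site amino-acid state patterns at the published positively
# selected COX1/COX2/COX3 sites across the 10-taxon comparison panel.
# States are ordered: Bos_taurus, Homo_sapiens, Caenorhabditis_elegans,
# Diploscapter_pachys, Diploscapter_coronatus, Bursaphelenchus_xylophilus,
# Panagrellus_redivivus, Halicephalobus_mephisto, Halicephalobus_gingivalis,
# Halicephalobus_consperatus.
# ref_site: bovine COX numbering; query_site: H. mephisto numbering.
# proximity: reported proton-channel proximity flag (within4/within13/none).
# chem_label: reported chemical-change class pair ('.' where none printed).
gene	branch	ref_site	query_site	states	proximity	chem_label	severity	syn_obs
COX1	D	29	36	VLVVVLLLLL	within13	nonpolar-nonpolar	low	yes
COX1	D	35	42	LLLNNMMMMM	within4	nonpolar-nonpolar	low	yes
COX1	D	39	46	AALLLFFFFF	within4	nonpolar-nonpolar	low	yes
COX1	D	46	53	TNFFFYYYYY	within13	nonpolar-polar	high	no
COX1	D	215	221	LLLLLIIIII	none	nonpolar-nonpolar	low	no
COX1	D	462	468	LLTNNVVVVV	within4	polar-nonpolar	high	yes
COX1	D	464	470	AAGGGSSSSS	within4	nonpolar-polar	high	yes
COX1	D	479	485	KKYYYFFFFF	within13	polar-nonpolar	high	yes
COX1	C	89	96	AAAAAASSSS	within13	nonpolar-polar	high	no
COX1	C	259	265	TTLIILMMMM	within4	nonpolar-nonpolar	low	no
COX1	C	270	276	YYASSSTTTT	within13	polar-polar	low	no
COX1	C	353	359	LILLLLIIII	within13	nonpolar-nonpolar	low	no
COX1	C	399	405	LLFFFLYYYY	within4	nonpolar-polar	high	no
COX1	C	403	409	YYYVVFLLLL	within13	nonpolar-nonpolar	low	no
COX1	C	441	447	SSLLLLMMMM	within13	nonpolar-nonpolar	low	yes
COX1	C	494	500	WWYVVNGGGG	within4	polar-nonpolar	medium	yes
COX1	C	495	501	LLCVAMSSSS	within13	nonpolar-polar	high	no
COX1	B	476	482	FFFFFFFMMM	within13	nonpolar-nonpolar	low	yes
COX2	C	94	97	SSNFYNQQQQ	none	.	low	no
COX3	D	156	153	RRRSSDDDDD	none	positive_or_polar-negative	high	no
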