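# Illustrative proton-pathway channel annotation in bovine COX1 (template)
# numbering.  This is a SYNTHETIC example subset built from well-known
# pathway-lining residues for demonstrations and tests; replace it with a
# complete curated list for real analyses.
pathway	chain	residue	frame
H	A	38	template
H	A	51	template
H	A	440	template
H	A	441	template
K	A	244	template
K	A	316	template
K	A	319	template
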