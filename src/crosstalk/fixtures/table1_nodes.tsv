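layer	id	degree	has_partners
mrna	INSR		true
mrna	NOS3		true
mrna	PPARG		true
mrna	SLC2A4		true
mrna	SOD2		true
mrna	HMOX1		true
mrna	TNF		true
mrna	INS		false
mrna	LEP		false
mirna	hsa-miR-3184-5p	4	true
mirna	hsa-miR-17-5p	4	true
mirna	hsa-miR-20a-5p	4	true
mirna	hsa-miR-93-5p	4	true
mirna	hsa-miR-106b-5p	4	true
mirna	hsa-miR-20b-5p	4	true
mirna	hsa-miR-200c-3p	4	true
lncrna	NEAT1	7	true
lncrna	XIST	7	true
lncrna	EBLN3P	7	true
lncrna	H19	6	true
lncrna	MALAT1	6	true
lncrna	HCG18	6	true
lncrna	PSMA3-AS1	6	true
lncrna	AC021078.1	6	true
lncrna	AC005261.1	6	true
lncrna	AC024940.6	6	true
lncrna	NORAD	6	true
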