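# Retroelement (Metaviridae gag/rve and ERV env)-derived domesticated genes with
# de novo gained introns (published survey transcription; 27 intron-containing genes
# of the 34 analyzed).  Locations: "A/B" = introns in both regions; "A or B" = introns
# in region A in some species and region B in others.  SCAND3 is the single
# retroelement fusion gene and is flagged as a fusion exception.
family_id	te_group	subgroup	progenitor_class	origin_route	fusion_exception	intron_location	intron_min	intron_max
RGAG1	chromovirus_MART	gag	retroelement	whole_TE	false	UTR5/CDS	3	3
ZCCHC16	chromovirus_MART	gag	retroelement	whole_TE	false	UTR5	2	6
ZCCHC5	chromovirus_MART	gag	retroelement	whole_TE	false	UTR5	1	1
PEG10	chromovirus_MART	gag	retroelement	whole_TE	false	UTR5 or CDS	1	2
LDOC1L	chromovirus_MART	gag	retroelement	whole_TE	false	UTR5	1	1
RGAG4	chromovirus_MART	gag	retroelement	whole_TE	false	UTR3	1	1
C22ORF29	chromovirus_MART	gag	retroelement	whole_TE	false	UTR5	2	2
FAM127B	chromovirus_MART	gag	retroelement	whole_TE	false	CDS	1	1
PNMA2	barthez_PNMA	gag	retroelement	whole_TE	false	UTR5	2	2
PNMA3	barthez_PNMA	gag	retroelement	whole_TE	false	UTR5	1	1
MOAP1	barthez_PNMA	gag	retroelement	whole_TE	false	UTR5	1	2
PNMA5	barthez_PNMA	gag	retroelement	whole_TE	false	UTR5 or UTR3	3	3
PNMA6A	barthez_PNMA	gag	retroelement	whole_TE	false	UTR5 or CDS	1	2
PNMA6B	barthez_PNMA	gag	retroelement	whole_TE	false	UTR5	1	1
ZCCHC12	barthez_PNMA	gag	retroelement	whole_TE	false	UTR5	3	3
ZCCHC18	barthez_PNMA	gag	retroelement	whole_TE	false	UTR5	2	2
CCDC8	barthez_PNMA	gag	retroelement	whole_TE	false	CDS	1	1
PNMAL1	barthez_PNMA	gag	retroelement	whole_TE	false	UTR5	2	2
PNMAL2	barthez_PNMA	gag	retroelement	whole_TE	false	CDS	1	1
ARC	osvaldo_ARC	gag	retroelement	whole_TE	false	UTR3	2	2
Gin1	rve	rve	retroelement	whole_TE	false	UTR5/CDS	7	7
SCAND3	rve	rve	retroelement	whole_TE	true	CDS	3	3
KRBA2	rve	rve	retroelement	whole_TE	false	UTR5 or CDS	1	3
NYNRIN	rve	rve	retroelement	whole_TE	false	UTR5/CDS	8	8
ERVFRD-1	ERV	env	retroelement	whole_TE	false	UTR5	1	1
ERVW-1	ERV	env	retroelement	whole_TE	false	UTR5	1	1
syncytin_b	ERV	env	retroelement	whole_TE	false	UTR5	2	2
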