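# Origin node (LCA) of each intron-containing domesticated gene on the packaged
# species tree (published phylogenomic survey transcription).  "Eutheria" is the
# LCA of placentals.  Genes from the gene tables that the survey left unplaced are
# not listed here and carry origin "unplaced" downstream.
family_id	origin_node
RGAG1	Eutheria
ZCCHC16	Eutheria
ZCCHC5	Eutheria
PEG10	Theria
LDOC1L	Eutheria
RGAG4	Eutheria
C22ORF29	Eutheria
PNMA2	Eutheria
PNMA3	Eutheria
MOAP1	Eutheria
PNMA5	Eutheria
PNMA6A	Eutheria
PNMA6B	Eutheria
ZCCHC12	Eutheria
ZCCHC18	Eutheria
CCDC8	Eutheria
PNMAL1	Eutheria
PNMAL2	Eutheria
ARC	Tetrapoda
SCAND3	Theria
KRBA2	Eutheria
NYNRIN	Theria
POGK	Amniota
ZBED1	Tetrapoda
ZNF862	Theria
Buster3	Eutheria
PRKRIR	Gnathostomata
THAP9	Gnathostomata
HARBI1	Gnathostomata
NAIF1	Gnathostomata
PGBD1	Eutheria
PGBD2	Theria
PGBD5	Chordata
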