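# Intron position conservation of Eutheria-specific domesticated genes across the
# four placental superorders (published survey transcription).  Values: present
# (position conserved), incomplete (assembly incomplete at the locus), unknown
# (state could not be determined).  The published table prints "C22OF29" for the
# gene given as C22ORF29 elsewhere; the normalized name is used here.
family_id	Euarchontoglires	Laurasiatheria	Xenarthra	Afrotheria
RGAG1	present	present	present	present
RGAG4	present	present	incomplete	present
ZCCHC5	present	present	present	present
LDOC1L	present	present	present	present
C22ORF29	present	present	present	present
PNMA2	present	present	present	present
PNMA3	present	present	incomplete	present
MOAP1	present	present	present	present
PNMA5	present	present	present	present
PNMA6A	present	unknown	unknown	present
ZCCHC12	present	present	present	present
PNMAL1	present	present	present	present
KRBA2	present	present	present	present
PGBD1	present	present	present	present
Buster3	present	present	present	present
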