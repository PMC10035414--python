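# Promoter cis-acting element catalog, v1.
# Patterns are IUPAC nucleotide codes taken from public PLACE/PlantCARE
# definitions; categories: growth_development | phytohormone | stress.
name	pattern	category	description
CAT-box	GCCACT	growth_development	meristem expression
O2-site	GATGAYRTGR	growth_development	zein metabolism regulation
RY-element	CATGCATG	growth_development	seed-specific regulation
GCN4_motif	TGAGTCA	growth_development	endosperm expression
HD-Zip1	CAATWATTG	growth_development	palisade mesophyll differentiation
AACA-motif	AACAAAC	growth_development	endosperm-specific negative expression
MSA-like	TCCAACGG	growth_development	cell cycle regulation
ABRE	ACGTG	phytohormone	abscisic acid responsive element
CGTCA-motif	CGTCA	phytohormone	MeJA responsiveness
TGACG-motif	TGACG	phytohormone	MeJA responsiveness
TCA-element	CCATCTTTTT	phytohormone	salicylic acid responsiveness
ARE	AAACCA	stress	anaerobic induction
MBS	CAACTG	stress	MYB binding site, drought inducibility
LTR	CCGAAA	stress	low-temperature responsiveness
GC-motif	CCCCCG	stress	anoxic specific inducibility
TC-rich	ATTTTCTTCA	stress	defense and stress responsiveness
ERE	ATTTCAAA	stress	oxidative stress responsiveness
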