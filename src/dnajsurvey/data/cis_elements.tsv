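# Default stress/hormone cis-element table for promoter scanning.
# The HSE core is the classical heat-shock element core; the remaining
# consensi are canonical published sequences for each element and are
# user-replaceable data, not a fixed vocabulary.
# Columns: name sequence category response
name	sequence	category	response
HSE	AAAAAATTTC	stress	heat
TC-rich	ATTTTCTTCA	stress	defense
LTR	CCGAAA	stress	low-temperature
MBS	CAACTG	stress	drought
TCA-element	CCATCTTTTT	hormone	SA
TGA-element	AACGAC	hormone	IAA
GARE-motif	TCTGTTG	hormone	GA
CGTCA-motif	CGTCA	hormone	MeJA
ABRE	ACGTGGC	hormone	ABA
ERE	ATTTCAAA	hormone	ethylene
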