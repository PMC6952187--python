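# name	recognition (caret marks the top-strand cut)
AvrII	C^CTAGG
BamHI	G^GATCC
BglII	A^GATCT
EcoRI	G^AATTC
EcoRV	GAT^ATC
HindIII	A^AGCTT
KpnI	GGTAC^C
MluI	A^CGCGT
NcoI	C^CATGG
NdeI	CA^TATG
NheI	G^CTAGC
NotI	GC^GGCCGC
PstI	CTGCA^G
SacI	GAGCT^C
SalI	G^TCGAC
SmaI	CCC^GGG
SpeI	A^CTAGT
SphI	GCATG^C
XbaI	T^CTAGA
XhoI	C^TCGAG
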