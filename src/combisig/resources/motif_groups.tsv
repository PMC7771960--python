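group	motif	dominance
RAR	RARA	RA_dominant
FOX	FOXA1	RA_dominant
FOX	FOXA2	RA_dominant
FOX	FOXA3	RA_dominant
FOX	FOXC2	RA_dominant
FOX	FOXD3	RA_dominant
ETS	SPI1	RA_dominant
ETS	SPIB	RA_dominant
ETS	SPIC	RA_dominant
ETS	EHF	RA_dominant
ETS	ELF1	RA_dominant
ETS	ELF2	RA_dominant
ETS	ELF3	RA_dominant
ETS	ELF4	RA_dominant
ETS	ELF5	RA_dominant
SMAD	SMAD3	TGFB_dominant
SMAD	SMAD4	TGFB_dominant
SMAD	SMAD9	TGFB_dominant
AP-1	JUN	TGFB_dominant
AP-1	JUNB	TGFB_dominant
AP-1	JUND	TGFB_dominant
AP-1	JDP2	TGFB_dominant
AP-1	FOS	TGFB_dominant
AP-1	FOSB	TGFB_dominant
AP-1	FOSL1	TGFB_dominant
AP-1	FOSL2	TGFB_dominant
AP-1	BACH1	TGFB_dominant
AP-1	BACH2	TGFB_dominant
AP-1	BATF	TGFB_dominant
SMARCC1	SMARCC1	TGFB_dominant
NFE	NFE2	TGFB_dominant
NFE	NFE2L2	TGFB_dominant
MAF	MAFF	TGFB_dominant
MAF	MAFK	TGFB_dominant
HOX	HOXA13	neither
HOX	HOXB13	neither
HOX	HOXC10	neither
HOX	HOXC12	neither
HOX	HOXC13	neither
HOX	HOXD13	neither
NFKB	NFKB1	neither
NFKB	REL	neither
NFKB	RELA	neither
CDX	CDX1	neither
CDX	CDX2	neither
CTCF	CTCF	neither
BCL	BCL11A	neither
BCL	BCL11B	neither
GRHL1	GRHL1	neither
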