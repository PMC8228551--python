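set_name	gene
up	APC
up	APP
up	ATG16L1
up	ATM
up	BCL2
up	BCL2L11
up	CCND1
up	CDKN1A
up	CDKN1B
up	CDKN1C
up	CRK
up	DDIT4
up	DICER1
up	DNMT1
up	E2F1
up	E2F5
up	EZR
up	FBXW7
up	FOS
up	FOXO1
up	FOXO3
up	HIPK2
up	IRS1
up	ITGA5
up	ITGB8
up	KAT2B
up	KRAS
up	MAFB
up	MAP2K1
up	MAP2K4
up	MAPK1
up	MAPK9
up	NFE2L2
up	NLK
up	NOTCH1
up	NTRK3
up	PTEN
up	PURA
up	RAP1B
up	RB1
up	RECK
up	RGS5
up	SIRT1
up	SMAD4
up	SMAD7
up	SOCS3
up	SP1
up	SP3
up	STAT3
up	STAT5A
up	TCEAL1
up	TCF4
up	TGFBR1
up	TGFBR2
up	THRB
up	TMED7
up	VEGFA
up	ZBTB4
down	ADD3
down	ANXA2
down	APC
down	ARID2
down	ARL6IP5
down	CAMTA1
down	CBFB
down	CCND1
down	CDH2
down	CDK4
down	CDK6
down	CDKN1A
down	CEBPA
down	CHRAC1
down	CPNE3
down	CSRP1
down	CTGF
down	CTNNB1
down	DDX6
down	DNAJB1
down	E2F3
down	EDN1
down	EGFR
down	EIF4E
down	ERG
down	ETS1
down	FLI1
down	FLOT2
down	FOXO3
down	FSCN1
down	FZD7
down	GNA13
down	GNAI2
down	GNAI3
down	GOLGA7
down	HCN2
down	IGF1R
down	IL6R
down	JAG1
down	JUP
down	KLF4
down	KRAS
down	LIN7C
down	LRP1
down	MECP2
down	MEF2A
down	MYC
down	NOTCH1
down	NRAS
down	NT5E
down	PDLIM7
down	PHC2
down	PICALM
down	PIK3CA
down	PODXL
down	PSIP1
down	PSMG1
down	PTBP1
down	PTBP2
down	PTEN
down	RAB11FIP2
down	RAC1
down	RHOA
down	ROCK1
down	SIRT1
down	SMAD3
down	SMAD4
down	SOX2
down	SOX9
down	SP1
down	SWAP70
down	SYNE1
down	TAGLN2
down	TP53
down	TPM1
down	TPM3
down	TWF1
down	VEGFA
down	YWHAZ
sn	BCL2
sn	CCND1
sn	CDKN1A
sn	CRK
sn	CXCR4
sn	DNMT1
sn	EGFR
sn	FBXW7
sn	FGFR1
sn	FOXO1
sn	FOXO3
sn	IGF1R
sn	IRS1
sn	KRAS
sn	MAPK1
sn	MYC
sn	PTBP2
sn	SIRT1
sn	SOX2
sn	SP1
sn	SP3
sn	VEGFA
putamen	APAF1
putamen	BCL2
putamen	CCND1
putamen	ETS1
putamen	FOXO3
putamen	ITPR1
putamen	MAFB
putamen	MAP2K1
putamen	MEIS1
putamen	MYC
putamen	PIK3R1
putamen	PTEN
putamen	SIRT1
putamen	SMAD4
putamen	SNAI1
putamen	SSX2IP
putamen	TCF12
putamen	THRB
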