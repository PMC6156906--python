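bradycardia	curated cardiac-conduction gene module	ADRB1	CYP2D6	KCNE1	KCNE2	KCNH2	KCNJ3	KCNQ1	SEMA3A
cardiomyopathy	curated cardiomyopathy gene module	ACE	ADORA1	ADORA2A	ADRA2C	ADRB2	ADRB3	AGT	AGTR1	AGTR2	APC	APOE	AR	CCL2	CHRM2	CTLA4	CYP2D6	EGFR	ESR1	ESR2	GPX1	HP	HTR2A	IFNG	IL10	IL1B	IL6	LTA	MAP2K1	NOS3	PPARGC1A	PSEN1	SLC6A2	SLC6A4	SOD2	STAT3	TGFB1	TNF	TTR	VEGFA
coronary_artery_disease	curated coronary artery disease gene module	ABCB1	ACE	ADIPOQ	ADM	ADORA2A	ADRA2C	AGER	AGT	AKAP13	AKT1	ANK3	APOE	ARNTL	BCL11A	BDNF	BSN	CACNA1C	CAPN10	CBS	CLOCK	CNR1	COMT	CRP	CYP1A2	CYP2C19	CYP2C9	CYP2D6	CYP3A4	CYP3A5	DBP	DLG2	EGR3	ENPP1	ESR1	F5	FGF2	FTO	GCLM	GRIA1	GRIK4	GSTM1	GSTP1	GSTT1	HFE	HLA-A	HLA-B	HNF4A	HP	HRH1	HTR2A	HTR2C	IL1B	IL1RN	IL6	IL6R	INSIG2	ITGB3	KCNN3	LEP	LEPR	LTA	MC4R	MMP3	MMP9	MTHFR	MTR	MTRR	NOS1	NOS3	NPAS2	NPY	NQO1	NR3C1	PDGFB	PDYN	PER1	PER2	PLA2G4A	PON1	PPARG	PRKAA1	PRKAA2	PRKAB1	PRKAB2	PRODH	PTGS1	PTGS2	RGS2	SIRT1	SLC22A3	SLC2A9	SLC6A4	SOD2	TBX1	TCF7L2	TNF	TNFRSF1B	TOMM40	VWF
major_depressive_disorder	curated major depressive disorder gene module	ACE	ADORA1	ADORA2A	ADRA2C	ADRB2	ADRB3	AGT	AGTR1	AGTR2	APC	APOE	AR	CCL2	CHRM2	CTLA4	CYP2D6	EGFR	ESR1	ESR2	GPX1	HP	HTR2A	IFNG	IL10	IL1B	IL6	LTA	MAP2K1	NOS3	PPARGC1A	PSEN1	SLC6A2	SLC6A4	SOD2	STAT3	TGFB1	TNF	TTR	VEGFA
psychotic_disorder	curated psychotic disorder gene module	ABCB1	ACE	ADIPOQ	ADM	ADORA2A	ADRA2C	AGER	AKAP13	AKT1	ANK3	APOE	ARNTL	BCL11A	BDNF	BSN	CACNA1C	CAPN10	CBS	CLOCK	CNR1	COMT	CRP	CYP1A2	CYP2C9	CYP2D6	CYP3A4	CYP3A5	DBP	DLG2	EGR3	ENPP1	ESR1	F5	FGF2	FTO	GCLM	GRIA1	GRIK4	GSTM1	GSTP1	GSTT1	HFE	HLA-A	HLA-B	HNF4A	HRH1	HTR2A	HTR2C	IL1B	IL1RN	IL6	INSIG2	KCNN3	LEP	LEPR	MC4R	MTHFR	MTR	MTRR	NOS1	NOS3	NPAS2	NPY	NQO1	NR3C1	PDGFB	PDYN	PER1	PER2	PLA2G4A	PON1	PPARG	PRKAA1	PRKAA2	PRKAB1	PRKAB2	PRODH	RGS2	SIRT1	SLC22A3	SLC2A9	SLC6A4	SOD2	TBX1	TCF7L2	TNF	TNFRSF1B	TOMM40	VWF
schizophrenia	curated schizophrenia gene module	ABCB1	ACE	ADRB1	AGT	CRP	CYP1A2	CYP2C19	CYP2C9	CYP2D6	CYP3A4	CYP3A5	ESR1	HP	IL1RN	IL6	IL6R	ITGB3	KCNE1	KCNE2	KCNH2	KCNJ3	KCNQ1	LTA	MMP3	MMP9	MTHFR	NOS3	NPY	PON1	PTGS1	PTGS2	SEMA3A	TNF
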