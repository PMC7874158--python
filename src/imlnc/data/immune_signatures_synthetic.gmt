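IFN-gamma response	synthetic stand-in gene list for the interferon-gamma response signature	IFNG	STAT1	STAT2	IRF1	IRF9	CXCL9	CXCL10	CXCL11	IDO1	GBP1	GBP2	HLA-DRA	HLA-DRB1	HLA-A	HLA-B	TAP1	TAP2	PSMB8	PSMB9	JAK2
Lymphocyte infiltration	synthetic stand-in gene list for the overall lymphocyte infiltration signature	CD2	CD3D	CD3E	CD3G	CD8A	CD8B	CD4	CD19	MS4A1	CD79A	CD79B	IL7R	LCK	ZAP70	CCL5	GZMA	GZMB	GZMK	PRF1	KLRB1
Macrophages-monocytes	synthetic stand-in gene list for the macrophages/monocytes signature	CD68	CD163	CSF1R	MSR1	MRC1	ITGAM	FCGR1A	FCGR3A	CD14	LYZ	AIF1	TYROBP	FCER1G	C1QA	C1QB	C1QC	MARCO	SIGLEC1	VSIG4	SLC11A1
TGF-beta response	synthetic stand-in gene list for the TGF-beta response signature	TGFB1	TGFB2	TGFB3	TGFBR1	TGFBR2	SMAD2	SMAD3	SMAD4	SMAD7	SKIL	SERPINE1	THBS1	LTBP1	LTBP2	ID1	ID2	JUNB	PMEPA1	BAMBI	CDKN1A
Wound healing	synthetic stand-in gene list for the wound healing signature	F3	PLAU	PLAUR	SERPINB2	FGF2	FGF7	VEGFA	PDGFA	PDGFB	COL1A1	COL1A2	COL3A1	FN1	MMP1	MMP2	MMP9	TIMP1	ITGA5	ITGB1	ACTA2
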