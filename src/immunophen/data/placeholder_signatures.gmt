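T_CELL	placeholder T-cell signature (replace with curated lists)	CD2	CD3D	CD3E	CD3G	CD8A	CD8B	CD28	LCK	ZAP70	IL7R	CCL5	GZMK	TRAC	TRBC1	THEMIS
B_CELL	placeholder B-cell signature (replace with curated lists)	CD19	MS4A1	CD79A	CD79B	BLNK	PAX5	IGHM	TNFRSF13B	BANK1	FCRL5	BLK	VPREB3
NK_CELL	placeholder NK-cell signature (replace with curated lists)	KLRD1	KLRF1	NCR1	NCR3	GNLY	NKG7	PRF1	KIR2DL3	FGFBP2	SPON2	XCL1	XCL2
MACROPHAGE	placeholder macrophage signature (replace with curated lists)	CD68	CD163	CSF1R	MSR1	MRC1	ITGAM	FCGR1A	SIGLEC1	C1QA	C1QB	VSIG4	SLC11A1
IMMUNE_SIGNATURE	placeholder pooled immune signature (IES; replace with curated lists)	CD2	CD3D	CD3E	CD3G	CD8A	CD8B	CD28	LCK	ZAP70	IL7R	CCL5	GZMK	TRAC	TRBC1	THEMIS	CD19	MS4A1	CD79A	CD79B	BLNK	PAX5	IGHM	TNFRSF13B	BANK1	FCRL5	BLK	VPREB3	KLRD1	KLRF1	NCR1	NCR3	GNLY	NKG7	PRF1	KIR2DL3	FGFBP2	SPON2	XCL1	XCL2	CD68	CD163	CSF1R	MSR1	MRC1	ITGAM	FCGR1A	SIGLEC1	C1QA	C1QB	VSIG4	SLC11A1	PTPRC	CD247	CD4	CTLA4	PDCD1	CD274	LAG3	TIGIT	IDO1	CXCL9	CXCL10	CXCL11	CCL19	CCL21	IFNG	GZMA	GZMB	TBX21	EOMES	STAT1
ACTIVATED_STROMA	placeholder activated-stroma / C-ECM signature (SES, NTP template; replace with curated lists)	ACTA2	TAGLN	COL1A1	COL1A2	COL3A1	COL5A1	COL5A2	COL6A3	COL11A1	FAP	FN1	SPARC	THBS2	POSTN	LUM	VCAN	FBN1	MMP2	MMP11	PDGFRB	INHBA	CTGF	SULF1	LOXL2	TNC
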