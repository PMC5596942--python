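mirna	partner	layer	mode
hsa-let-7a-5p	EIF2C2	tf	A
hsa-let-7a-5p	FSH	tf	R
hsa-let-7a-5p	MYC	tf	R
hsa-let-7a-5p	TRIM32	tf	A
hsa-let-7a-5p	E2F1	tf	A
hsa-let-7a-5p	E2F3	tf	A
hsa-let-7a-5p	LIN28	tf	R
hsa-let-7a-5p	LIN28B	tf	R
hsa-let-7a-5p	NFKB1	tf	A
hsa-let-7a-5p	FLI1	tf	A
hsa-let-7a-5p	CEBPA	tf	unknown
hsa-let-7a-5p	n410470	lncrna	unknown
hsa-let-7a-5p	HRAS	gene	unknown
hsa-let-7b-5p	EIF2C2	tf	A
hsa-let-7b-5p	MYC	tf	R
hsa-let-7b-5p	TRIM32	tf	A
hsa-let-7b-5p	LIN28	tf	R
hsa-let-7b-5p	LIN28B	tf	R
hsa-let-7b-5p	NFKB1	tf	A
hsa-let-7b-5p	n339682	lncrna	unknown
hsa-let-7b-5p	XIST	lncrna	unknown
hsa-let-7b-5p	n410735	lncrna	unknown
hsa-let-7b-5p	n410470	lncrna	unknown
hsa-let-7b-5p	CBFB	gene	unknown
hsa-let-7b-5p	IDI1	gene	unknown
hsa-let-7b-5p	PSME3	gene	unknown
hsa-let-7b-5p	SMARCC1	gene	unknown
hsa-miR-103a-3p	n406427	lncrna	unknown
hsa-miR-103a-3p	n410632	lncrna	unknown
hsa-miR-103a-3p	n407114	lncrna	unknown
hsa-miR-103a-3p	n342319	lncrna	unknown
hsa-miR-103a-3p	n410010	lncrna	unknown
hsa-miR-103a-3p	n409184	lncrna	unknown
hsa-miR-103a-3p	n344659	lncrna	unknown
hsa-miR-103a-3p	TTC28-AS1	lncrna	unknown
hsa-miR-103a-3p	n338391	lncrna	unknown
hsa-miR-103a-3p	n339003	lncrna	unknown
hsa-miR-103a-3p	n342913	lncrna	unknown
hsa-miR-103a-3p	n407911	lncrna	unknown
hsa-miR-103a-3p	n409072	lncrna	unknown
hsa-miR-103a-3p	n409093	lncrna	unknown
hsa-miR-103a-3p	KPNA1	gene	unknown
hsa-miR-103a-3p	NSF	gene	unknown
hsa-miR-125a-5p	EGR1	tf	unknown
hsa-miR-125a-5p	TLR2	tf	unknown
hsa-miR-125a-5p	n406658	lncrna	unknown
hsa-miR-125a-5p	DUSP3	gene	unknown
hsa-miR-128	n410586	lncrna	unknown
hsa-miR-128	n406663	lncrna	unknown
hsa-miR-128	n408020	lncrna	unknown
hsa-miR-128	ATP6V1C1	gene	unknown
hsa-miR-128	GNB5	gene	unknown
hsa-miR-128	TXNIP	gene	unknown
hsa-miR-128	UBE2N	gene	unknown
hsa-miR-15a-5p	c-myb	tf	A
hsa-miR-15a-5p	MYC	tf	R
hsa-miR-15a-5p	PRKCA	tf	R
hsa-miR-15a-5p	E2F1	tf	A
hsa-miR-15a-5p	E2F3	tf	A
hsa-miR-15a-5p	STAT5	tf	R
hsa-miR-15a-5p	n342249	lncrna	unknown
hsa-miR-15a-5p	n409656	lncrna	unknown
hsa-miR-15a-5p	n407055	lncrna	unknown
hsa-miR-15a-5p	n410632	lncrna	unknown
hsa-miR-15a-5p	n408096	lncrna	unknown
hsa-miR-15a-5p	n381271	lncrna	unknown
hsa-miR-15a-5p	n410476	lncrna	unknown
hsa-miR-15a-5p	HSPA1A	gene	unknown
hsa-miR-15a-5p	TPI1	gene	unknown
hsa-miR-16-5p	MYC	tf	R
hsa-miR-16-5p	E2F1	tf	A
hsa-miR-16-5p	E2F3	tf	A
hsa-miR-16-5p	STAT5	tf	R
hsa-miR-16-5p	NFKB1	tf	unknown
hsa-miR-16-5p	n340911	lncrna	unknown
hsa-miR-16-5p	n409656	lncrna	unknown
hsa-miR-16-5p	n409286	lncrna	unknown
hsa-miR-16-5p	n324249	lncrna	unknown
hsa-miR-16-5p	n409199	lncrna	unknown
hsa-miR-16-5p	n410507	lncrna	unknown
hsa-miR-16-5p	n409266	lncrna	unknown
hsa-miR-16-5p	ARHGDIA	gene	unknown
hsa-miR-16-5p	CYCS	gene	unknown
hsa-miR-16-5p	HSPA1A	gene	unknown
hsa-miR-16-5p	KPNA1	gene	unknown
hsa-miR-16-5p	L1CAM	gene	unknown
hsa-miR-16-5p	LARP	gene	unknown
hsa-miR-16-5p	NSF	gene	unknown
hsa-miR-16-5p	PCMT1	gene	unknown
hsa-miR-16-5p	PSME3	gene	unknown
hsa-miR-16-5p	TPI1	gene	unknown
hsa-miR-19b-3p	E2F1	tf	A
hsa-miR-19b-3p	MYC	tf	A
hsa-miR-19b-3p	MYCN	tf	A
hsa-miR-19b-3p	NKX2-5	tf	A
hsa-miR-19b-3p	TLX1	tf	A
hsa-miR-19b-3p	TLX3	tf	A
hsa-miR-19b-3p	ERS1	tf	A
hsa-miR-19b-3p	STAT5	tf	A
hsa-miR-19b-3p	SPI1	tf	R
hsa-miR-19b-3p	n336002	lncrna	unknown
hsa-miR-19b-3p	n341479	lncrna	unknown
hsa-miR-19b-3p	n409083	lncrna	unknown
hsa-miR-19b-3p	n339644	lncrna	unknown
hsa-miR-19b-3p	n333000	lncrna	unknown
hsa-miR-19b-3p	n339682	lncrna	unknown
hsa-miR-19b-3p	n333732	lncrna	unknown
hsa-miR-19b-3p	n337982	lncrna	unknown
hsa-miR-19b-3p	n340675	lncrna	unknown
hsa-miR-19b-3p	ATP6V1C1	gene	unknown
hsa-miR-19b-3p	LRP8	gene	unknown
hsa-miR-19b-3p	TOM1L2	gene	unknown
hsa-miR-24-3p	BMP2	tf	A
hsa-miR-24-3p	TGFB1	tf	R
hsa-miR-24-3p	PDGF	tf	unknown
hsa-miR-24-3p	RUNX2	tf	R
hsa-miR-24-3p	EGR1	tf	unknown
hsa-miR-24-3p	ESR2	tf	A
hsa-miR-24-3p	n340600	lncrna	unknown
hsa-miR-24-3p	n409298	lncrna	unknown
hsa-miR-24-3p	CTDSP2	gene	unknown
hsa-miR-24-3p	NFKBIA	gene	unknown
hsa-miR-24-3p	PSME3	gene	unknown
hsa-miR-30a-5p	EGR1	tf	unknown
hsa-miR-30a-5p	ESR2	tf	R
hsa-miR-30a-5p	n336002	lncrna	unknown
hsa-miR-30a-5p	n409199	lncrna	unknown
hsa-miR-30a-5p	RP11-46M12.1	lncrna	unknown
hsa-miR-30a-5p	ATP6V1C1	gene	unknown
hsa-miR-30a-5p	CBFB	gene	unknown
hsa-miR-30a-5p	KPNA1	gene	unknown
hsa-miR-30a-5p	NDE1	gene	unknown
hsa-miR-30a-5p	PRPF4B	gene	unknown
hsa-miR-30a-5p	YWHAZ	gene	unknown
hsa-miR-34a-5p	MYC	tf	R
hsa-miR-34a-5p	TP53	tf	A
hsa-miR-34a-5p	NR1H4	tf	R
hsa-miR-34a-5p	CEBPA	tf	unknown
hsa-miR-34a-5p	NFKB1	tf	A
hsa-miR-34a-5p	TP73	tf	A
hsa-miR-34a-5p	SNAI1	tf	R
hsa-miR-34a-5p	ZEB1	tf	R
hsa-miR-34a-5p	E2F3	tf	unknown
hsa-miR-34a-5p	n406642	lncrna	unknown
hsa-miR-34a-5p	n385777	lncrna	unknown
hsa-miR-34a-5p	n408346	lncrna	unknown
hsa-miR-34a-5p	n341213	lncrna	unknown
hsa-miR-34a-5p	n408077	lncrna	unknown
hsa-miR-34a-5p	n410211	lncrna	unknown
hsa-miR-34a-5p	n335724	lncrna	unknown
hsa-miR-34a-5p	HSPA1A	gene	unknown
hsa-miR-34a-5p	KPNA1	gene	unknown
hsa-miR-34a-5p	LARP	gene	unknown
hsa-miR-34a-5p	SMARCC1	gene	unknown
hsa-miR-34a-5p	TXNIP	gene	unknown
hsa-miR-7-5p	HoxD10	tf	A
hsa-miR-7-5p	SF2/ASF	tf	A
hsa-miR-7-5p	FOXP3	tf	A
hsa-miR-7-5p	n342007	lncrna	unknown
hsa-miR-7-5p	n407908	lncrna	unknown
hsa-miR-7-5p	n410669	lncrna	unknown
hsa-miR-7-5p	n410711	lncrna	unknown
hsa-miR-7-5p	GLS	gene	unknown
hsa-miR-7-5p	PSME3	gene	unknown
hsa-miR-7-5p	SNCA	gene	unknown
hsa-miR-9-5p	IL1B	tf	A
hsa-miR-9-5p	LPS	tf	A
hsa-miR-9-5p	NFKB1	tf	A
hsa-miR-9-5p	TLR2	tf	A
hsa-miR-9-5p	TLR4	tf	A
hsa-miR-9-5p	TLR7	tf	A
hsa-miR-9-5p	TLR8	tf	A
hsa-miR-9-5p	TLX	tf	R
hsa-miR-9-5p	TNF	tf	A
hsa-miR-9-5p	MYC	tf	A
hsa-miR-9-5p	CREB1	tf	unknown
hsa-miR-9-5p	REST	tf	unknown
hsa-miR-9-5p	YTHDF3	lncrna	unknown
hsa-miR-9-5p	OPTN	gene	unknown
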