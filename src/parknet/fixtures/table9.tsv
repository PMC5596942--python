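mirna	snp	population	p	chrom_pos	gene
hsa-miR-34a-5p	rs3750625	YRI	5.00E-05	10:112839601	ADRA2A
hsa-miR-34b-5p	rs3750625	YRI	5.00E-05	10:112839601	ADRA2A
hsa-miR-34c-5p	rs3750625	YRI	5.00E-05	10:112839601	ADRA2A
hsa-miR-29b-2-5p	rs1697406	YRI	9.00E-05	1:21904267	ALPL
hsa-miR-9-5p	rs1697406	YRI	9.00E-05	1:21904267	ALPL
hsa-miR-1225-5p	rs535860	YRI	1.00E-05	11:117159878	BACE1
hsa-miR-661	rs535860	YRI	1.00E-05	11:117159878	BACE1
hsa-miR-647	rs13198420	CEU	7.00E-05	6:38139482	BTBD9
hsa-miR-661	rs12206712	CEU	8.00E-05	6:38139748	BTBD9
hsa-miR-455-3p	rs2762934	YRI	1.00E-05	20:52771261	CYP24A1
hsa-miR-632	rs3814309	CEU	4.00E-06	1:110277403	GSTM3
hsa-miR-199b-5p	rs16843618	YRI	1.00E-05	2:210595820	MAP2
hsa-miR-663b	rs3766286	YRI	3.00E-05	1:31344250	SDC3
hsa-let-7a-3p	rs1050955	YRI	1.00E-05	7:100782460	SERPINE1
hsa-let-7b-3p	rs1050955	YRI	1.00E-05	7:100782460	SERPINE1
hsa-let-7f-1-3p	rs1050955	YRI	1.00E-05	7:100782460	SERPINE1
hsa-miR-612	rs7242	YRI	4.00E-05	7:100781445	SERPINE1
hsa-miR-224-5p	rs12281100	YRI	7.00E-05	11:36506773	TRAF6
hsa-miR-1226-3p	rs2242437	YRI	6.00E-07	19:1065563	HMHA1
hsa-miR-130a-5p	rs1042364	CEU	4.00E-05	4:100045574	ADH4
hsa-miR-29a-3p	rs1051881	YRI	9.00E-05	4:122737965	CCNA2
hsa-miR-29b-3p	rs1051881	YRI	9.00E-05	4:122737965	CCNA2
hsa-miR-29c-3p	rs1051881	YRI	9.00E-05	4:122737965	CCNA2
hsa-miR-1253	rs17085675	YRI	4.00E-05	5:95727664	PCSK1
hsa-miR-30b-3p	rs1045968	CEU	4.00E-05	16:29826365	PRRT2
hsa-miR-612	rs281437	YRI	4.00E-05	19:10397238	ICAM1
hsa-miR-663b	rs3829972	YRI	2.00E-05	12:6929018	CD4
hsa-miR-374a-5p	rs8067	YRI	1.00E-05	9:95218829	ASPN
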