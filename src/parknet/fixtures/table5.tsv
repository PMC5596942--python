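hub_gene	mirna	pd_specific	lncrnas
MAGED1	hsa-miR-3942-5p	0
MAGED1	hsa-miR-4703-5p	0
MAGED1	hsa-miR-3157-5p	0
MAGED1	hsa-miR-3188	0
MAGED1	hsa-miR-4649-3p	0
MAGED1	hsa-miR-3200-5p	0
MAGED1	hsa-miR-1252	0
MAGED1	hsa-miR-4777-5p	0
MAGED1	hsa-miR-760	0
MAGED1	hsa-miR-4474-3p	0
MAGED1	hsa-miR-4709-5p	0
MAGED1	hsa-miR-421	0	n339122
MAGED1	hsa-miR-505	0
MAGED1	hsa-miR-4704-3p	0
MAGED1	hsa-miR-4252	0
MAGED1	hsa-miR-3120-3p	0
MAGED1	hsa-miR-3148	0
MAGED1	hsa-miR-4457	0
MAGED1	hsa-miR-4801	0
MAGED1	hsa-miR-4731-3p	0
MAGED1	hsa-miR-548o	0
MAGED1	hsa-miR-4762-3p	0
MAGED1	hsa-miR-450b-5p	0
MAGED1	hsa-miR-1323	0
AP3B2	hsa-miR-221	0	n339827
AP3B2	hsa-miR-222	0
STXBP1	hsa-miR-9	1
AF1Q	hsa-let-7b	1	n339682;XIST;n410735;n410470;n408209;n410533;n410111;n411752;n381104;n333512;n345604;RP11-139H15.1;n407908
AF1Q	hsa-miR-1-2	0
AF1Q	hsa-miR-1-1	0
AF1Q	hsa-miR-155	0
AF1Q	hsa-miR-16-1	1
AF1Q	hsa-miR-16-2	1
AF1Q	hsa-miR-30a	1	n336002;n409199;RP11-46M12.1
AF1Q	hsa-miR-30b	1
AF1Q	hsa-miR-30c-1	1
AF1Q	hsa-miR-30c-2	1
AF1Q	hsa-miR-30d	0
AF1Q	hsa-miR-30e	0	n340869;n409200
AF1Q	hsa-miR-29a	1
AF1Q	hsa-miR-29c	1
AF1Q	hsa-miR-29b	1	n410507;n341043
GASP	hsa-miR-873	0
GASP	hsa-miR-4711-5p	0
GASP	hsa-miR-4642	0
GASP	hsa-miR-3065-5p	0
GASP	hsa-miR-3671	0
GASP	hsa-miR-4277	0
GASP	hsa-miR-888	0
GASP	hsa-miR-4727-5p	0
C14ORF78	hsa-miR-195	0
C14ORF78	hsa-miR-16	1	n340911;n409656;n409286;n324249;n409199;n410507;n409266;n410476;n407230;n340530;n407036
C14ORF78	hsa-miR-424	0	RP11-690G19.3;n410128;XIST;n342875;n381422;n406658;n340847;n338391;n407096;n342697;n382508;n407461;n339766
C14ORF78	hsa-miR-15a	1	n342249;n409656;n407055;n410632;n408096;n381271;n410476;n342731;n410126;n406625;n335593;n341454;n409264;n409159;n408379;n337715;n338629;n409761
C14ORF78	hsa-miR-497	0
C14ORF78	hsa-miR-15b	0	n410890;n410438;n338345
MAN1C1	hsa-miR-93-5p	0	n341008;n410211;n408146
MAN1C1	hsa-miR-130b-3p	0	n406921;n337752;n382094;n342786;n337985;n333016;n410686;n410036;n340556;n406580;n385717;n324749;n333275;n340852
MAN1C1	hsa-miR-206	0
MAN1C1	hsa-miR-1	1
MAN1C1	hsa-miR-613	0
HNRPC	hsa-miR-455-5p	0
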