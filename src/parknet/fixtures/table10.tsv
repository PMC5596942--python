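snp	functional_category	allele	region
rs3750625	transcriptional_regulation	C/A	3 prime UTR
rs1697406	transcriptional_regulation	A/G	3 prime UTR
rs535860	conserved	A/T	3 prime UTR
rs13198420	none	T/C	3 prime UTR
rs12206712	none	T/C	3 prime UTR
rs2762934	transcriptional_regulation	A/G	3 prime UTR
rs3814309	transcriptional_regulation;conserved	T/C	3 prime UTR
rs16843618	transcriptional_regulation	G/C	3 prime UTR
rs3766286	transcriptional_regulation;conserved	C/T	3 prime near gene
rs1050955	transcriptional_regulation	G/A	downstream
rs7242	transcriptional_regulation	T/G	3 prime UTR
rs12281100	none	A/C	downstream
rs2242437	none	C/G	upstream
rs1042364	protein_coding	A/G	3 prime UTR
rs1051881	protein_coding;splicing_regulation;transcriptional_regulation;post_translation	G/C	nonsynonymous
rs17085675	transcriptional_regulation	A/T	3 prime UTR
rs1045968	transcriptional_regulation	G/T	intron, 3 prime UTR
rs281437	transcriptional_regulation	C/T	3 prime UTR
rs3829972	transcriptional_regulation	A/G	3 prime UTR
rs8067	transcriptional_regulation	C/A	Regulatory region, 3 prime UTR
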