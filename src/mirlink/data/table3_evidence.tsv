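Database	Mature Mirna acc	Mature Mirna ID	Target Symbol	Target Entrez	Target Ensembl	Type	Pubmed ID	Score
mirtarbase	MIMAT0000275	hsa-miR-218-5p	ATM	472	ENSG00000149311	validated	23212916
mirtarbase	MIMAT0002816	hsa-miR-494-3p	BCL2	596	ENSG00000171791	validated	24960059
mirtarbase	MIMAT0000275	hsa-miR-218-5p	DDX6	1656	ENSG00000110367	validated	23212916
mirtarbase	MIMAT0000275	hsa-miR-218-5p	GOLGA3	2802	ENSG00000090615	validated	23212916
mirtarbase	MIMAT0002816	hsa-miR-494-3p	REST	5978	ENSG00000084093	validated	23446348
mirtarbase	MIMAT0000275	hsa-miR-218-5p	KCNK6	9424	ENSG00000099337	validated	23313552
mirtarbase	MIMAT0000275	hsa-miR-218-5p	ARSG	22901	ENSG00000141337	validated	23622248
mirtarbase	MIMAT0000275	hsa-miR-218-5p	MB21D2	151963	ENSG00000180611	validated	23212916
tarbase	MIMAT0000275	hsa-miR-218-5p	REST	5978	ENSG00000084093	validated	20371350
tarbase	MIMAT0003180	hsa-miR-487b-3p	SGMS2	166929	ENSG00000164023	validated	24038734
tarbase	MIMAT0002816	hsa-miR-494-3p	CPNE1	8904	ENSG00000214078	validated	25653011
tarbase	MIMAT0004672	hsa-miR-106b-3p	SCPEP1	59342	ENSG00000121064	validated	22291592
diana_microt	MIMAT0000275	hsa-miR-218-5p	DUSP5	1847	ENSG00000138166	predicted		0.992
diana_microt	MIMAT0002816	hsa-miR-494-3p	SGMS2	166929	ENSG00000164023	predicted		0.978
diana_microt	MIMAT0002816	hsa-miR-494-3p	INPP4B	8821	ENSG00000109452	predicted		0.889
diana_microt	MIMAT0002816	hsa-miR-494-3p	GATAD2B	57459	ENSG00000143614	predicted		0.85
elmmo	MIMAT0000275	hsa-miR-218-5p	TTC39C	125488	ENSG00000168234	predicted		0.712
elmmo	MIMAT0000275	hsa-miR-218-5p	SEMA4A	64218	ENSG00000196189	predicted		0.63
elmmo	MIMAT0000275	hsa-miR-218-5p	SORL1	6653	ENSG00000137642	predicted		0.533
elmmo	MIMAT0002816	hsa-miR-494-3p	GATAD2B	57459	ENSG00000143614	predicted		0.505
elmmo	MIMAT0002816	hsa-miR-494-3p	SORL1	6653	ENSG00000137642	predicted		0.504
diana_microt	MIMAT0004767	hsa-miR-193b-5p	PLXDC1	57125	ENSG00000161381	predicted		0.831
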