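# Ossamycin (oss) biosynthetic gene cluster, S. hygroscopicus var. ossamyceticus:
# 27 contiguous ORFs over ~127 kbp. Cluster accession printed both as MH763624
# and MH7636247 in the source literature; both strings are recorded here and
# neither is resolved programmatically.
name	length_aa	proposed_function	ncbi_hit	accession
OssA9	260	Thioesterase	S. sp. MA5143a (94%)	WP_107466330.1
OssA5	2192	Polyketide synthase	S. sp. MA5143a (87%)	WP_107466329.1
OssA6	2214	Polyketide synthase	EbeB, K. aburaviensis (56%)	AGY62754.1
OssR	865	LuxR family transcriptional regulator	S. torulosus (77%)	WP_055712771.1
OssX1	69	Hypothetical protein	S. sp. MA5143a (85%)	WP_107466326.1
OssC	455	Crotonyl-CoA reductase	S. torulosus (98%)	WP_055712773.1
OssD	330	Ketoacyl-ACP synthase III	S. bottropensis (96%)	WP_005483819.1
OssL	404	Cytochrome P450	S. bottropensis (83%)	WP_020115058.1
OssK	404	Cytochrome P450	S. bottropensis (92%)	WP_005483816.1
OssO	176	Spirocyclase	OlmO, S. avermitilis (43%)	WP_010984323.1
OssA1	3194	Polyketide synthase	S. sp. cf124 (71%)	WP_107439495.1
OssA2	3691	Polyketide synthase	NimA1, S. nanchangensis (57%)	AAS46341.1
OssA3	4306	Polyketide synthase	TamAl, S. sp. 307-9 (57%)	ADC79637.1
OssA4	3227	Polyketide synthase	TgaA, Sorangium cellulosum (49%)	ADH04639.1
OssM	400	Cytochrome P450	S. sp. MA5143a (90%)	WP_107468069.1
OssA7	3015	Polyketide synthase	NimA1, S. nanchangensis (55%)	AAS46341.1
OssA8	3594	Polyketide synthase	S. sp. MA5143a (84%)	WP_107467267.1
OssT	333	NDP-hexose-3-ketoreductase	ChlC4, S. antibioticus (58%)	AAZ77681.1
OssS	452	NDP-hexose-2,3-dehydratase	PgaS, S. sp. PGA64 (53%)	AHW57789.1
OssF	396	Cytochrome P450	S. sp. MA5143a (87%)	WP_107467265.1
OssZ1	198	dTDP-4-keto-6-deoxyhexose 3,5-epimerase	AknL, S. galilaeus (58%)	AAF70101.1
OssI	251	SAM-dependent methyltransferase	BusS, Saccharopolyspora pogona (61%)	AAY88936.1
OssJ	380	dTDP-4-amino-4,6-dideoxygalactose transaminase	S. sp. cf124 (83%)	SFN43901.1
OssQ	439	NDP-hexose 3,4-dehydratase	UrdQ, S. fradiae (81%)	AAF72550.1
OssGT	413	Glycosyltransferase	NivK, S. sp. Ls2151 (47%)	AGZ78380.1
OssX2	421	serine hydroxymethyltransferase	S. torulosus (98%)	WP_055716418.1
OssT	423	ABC transporter	S. torulosus (99%)	WP_055717176.1
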