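description	length	gc_percent	control	nacl	tmac
Telomere (TTTAGGG)n		42.9	16068	38	132
(CAA)n		33.3	1202	697	571
(GAA)n		33.3	337	77	103
centromeric tandem-9 DIMER	340	37.1	8200	3881	5595
18S rRNA AH001680	1068	47.2	9750	1203	1719
28S rRNA AH001681	444	57.9	2393	114	281
Lsat_XCons_Pol_2012_05	5093	41.8	601915	121242	209480
Lsat_XCons_B449_2012_05	5888	35.5	827744	134225	198431
Lsat_MARPT_Cont_36	209	38.3	13938	2543	3822
Lsat_MARPT_Cont_49	321	52.0	5133	307	658
Lsat_MARPT_Cont_54	217	32.7	36184	3347	9905
Lsat_MARPT_Cont_61	238	38.2	27179	5034	6901
Lsat_MARPT_Cont_65	260	37.7	45522	10213	18782
Lsat_MARPT_Cont_70	185	45.4	10256	1094	2338
Lsat_MARPT_Cont_74	217	33.6	21219	2212	2480
Lsat_MARPT_Cont_82	197	25.4	12971	5597	7227
Lsat_MARPT_Cont_83	181	32.6	10414	1184	1482
Lsat_MARPT_Cont_91	255	39.6	17399	3380	4904
Lsat_MARPT_Cont_94	240	43.8	43818	2329	8788
Lsat_MARPT_Cont_95	188	38.3	13236	2808	3342
Lsat_MARPT_Cont_113	223	41.3	12213	3110	4310
Lsat_MARPT_Cont_124	211	49.3	2141	215	373
Lsat_MARPT_Cont_138	198	41.4	17234	3850	5503
Lsat_MARPT_Cont_142	235	41.3	26304	3402	5911
Lsat_MARPT_Cont_144	362	47.5	6408	619	1014
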