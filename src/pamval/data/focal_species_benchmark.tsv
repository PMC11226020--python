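scientific_name	common_name	total_detections	max_confidence	precision_c10	p10_tp	p10_n	precision_c25	max_fp_confidence	recall	recall_tp	recall_n	f_score	ssc
Spinus tristis	American Goldfinch	4004	0.999	0.967	58	60	1.000	0.186	1.000	1	1	0.983	0.100
Turdus migratorius	American Robin	75153	0.999	0.933	56	60	0.939	0.551	0.500	1	2	0.651	0.100
Hirundo rustica	Barn Swallow	9046	0.999	0.950	57	60	1.000	0.195					0.100
Passerina caerulea	Blue Grosbeak	26670	0.999	0.683	41	60	0.879	0.914	1.000	1	1	0.812	0.250
Cyanocitta cristata	Blue Jay	6539	0.999	0.983	59	60	1.000	0.206	0.667	2	3	0.795	0.100
Quiscalus quiscula	Common Grackle	8407	0.998	0.867	52	60	0.939	0.574	1.000	1	1	0.929	0.100
Chordeiles minor	Common Nighthawk	26179	0.998	1.000	60	60	1.000	0.100	1.000	1	1	1.000	0.100
Spiza americana	Dickcissel	397405	0.997	0.933	56	60	1.000	0.200	0.588	10	17	0.722	0.100
Tyrannus tyrannus	Eastern Kingbird	28748	0.997	1.000	60	60	1.000	0.100	1.000	1	1	1.000	0.100
Ammodramus savannarum	Grasshopper Sparrow	956111	0.996	0.533	32	60	0.652	0.448	0.800	4	5	0.640	0.448
Eremophila alpestris	Horned Lark	581287	0.996	0.817	49	60	0.955	0.628	0.833	5	6	0.825	0.250
Zenaida macroura	Mourning Dove	31117	0.995	0.867	52	60	0.974	0.293	0.500	1	2	0.634	0.100
Colinus virginianus	Northern Bobwhite	34608	0.995	0.817	49	60	1.000	0.227	1.000	1	1	0.899	0.250
Agelaius phoeniceus	Red-winged Blackbird	148573	0.997	0.967	58	60	1.000	0.129	0.600	3	5	0.740	0.100
Phasianus colchicus	Ring-necked Pheasant	13152	0.999	0.967	58	60	0.962	0.717	0.760	19	25	0.851	0.100
Passerculus sandwichensis	Savannah Sparrow	4439	0.998	0.567	34	60	0.889	0.494	0.500	1	2	0.531	0.250
Tachycineta bicolor	Tree Swallow	7637	0.996	0.117	7	60	0.333	0.505					0.505
Tyrannus verticalis	Western Kingbird	4958	0.999	0.917	55	60	0.959	0.711					0.100
Sturnella neglecta	Western Meadowlark	1331498	0.999	0.650	39	60	0.821	0.598	0.867	13	15	0.743	0.250
Meleagris gallopavo	Wild Turkey	4083	0.999	0.800	48	60	0.923	0.653	1.000	1	1	0.889	0.250
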