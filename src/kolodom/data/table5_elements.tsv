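subfamily	cds	cds_locus	element_locus	length	tir_left	tir_right	tsd_left	tsd_right
A1	Tr21	Chr04:107657217..107659511(+)	Chr04:107650836..107663091(+)	12216	AGCGATTCTGACATGG	AGTGATACTGACAGTA	TTAA	TTAA
A1	Tr22	Chr01:168455606..168457900(-)	Chr01:168451382..168460584(-)	9163	AGCGATTCTGACATGG	AGTGATACTGACAGTA	TTAA	TTAA
A1	Tr23	Chr03:106168762..106171056(-)	Chr03:106165634..106173458(-)	7785	AGCGATTCTGACATGG	AGTGATACTGACAGTA	TTAA	TTAA
A2	Tr8	Chr08:54548260..54550611(+)	Chr08:54546557..54553359(+)	6763	AGGAGAAGGAAAGGCT	AGGAAATGGCAAGCCA	TTAA	TTAA
A2	Tr11	scaffold_609:18293..20635(-)	scaffold_609:15284..22344(-)	7021	AGGAGAAGGAAAGGCT	AGGAAATGGCAAGCCA	TTAA	ATAA
A3	Tr14	scaffold_51:231432..233759(-)	scaffold_51:227047..240993(-)	13907	AGGACATGTCAACCCC	AGGACGTGTCAACCCT	TTAA	TTAA
A3	Tr15	Chr01:83498100..83500424(+)	Chr01:83495893..83504753(+)	8821	AGGACATGTCAACCCC	AGGACGTGTCAACCAT	TTAA	TTAA
A4	Tr25	Chr01:107512548..107514821(+)	Chr01:107510216..107521330(+)	11075	AGGACAAGGAAAGCTT	AGGAAAATGAAAGTCA	TTAA	TTAA
A5	Tr2	Chr02:100830975..100833458(+)	Chr02:100828018..100838339(+)	10282	AGGGGAACTATCATGA	AGGGGATCTATCATGA	TTAA	TTAA
A6	Tr9	Chr02:55486066..55488417(+)	Chr02:55483392..55492644(+)	9213	AGAGCAAGTAAAGTCG	AGAGCAAGGCAAGCTT	TTAA	TTAA
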