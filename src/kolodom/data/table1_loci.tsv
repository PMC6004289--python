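name	species	locus	longest_orf_nt	trimmed_nt	n_truncated	semi_evidence
Tr1	tropicalis	Chr05:4592573..4595167(-)	2595	2202	1	0
Tr2	tropicalis	Chr02:100830975..100833458(+)	2484	2421	3	0
Tr3	tropicalis	Chr01:90056839..90059247(+)	2409	2409	0	0
Tr4	tropicalis	Chr09:49289527..49291908(+)	2382	2319	0	0
Tr5	tropicalis	scaffold_769:44126..46486(-)	2361	2361	10	0
Tr6	tropicalis	scaffold_3164:2182..4536(-)	2355	2355	5	0
Tr7	tropicalis	Chr02:77614330..77616681(-)	2352	2352	2	0
Tr8	tropicalis	Chr08:54548260..54550611(+)	2352	2352	9	0
Tr9	tropicalis	Chr02:55486066..55488417(+)	2352	2352	2	0
Tr10	tropicalis	Chr08:50277255..50279597(+)	2343	2292	0	0
Tr11	tropicalis	scaffold_609:18293..20635(-)	2343	2343	9	0
Tr12	tropicalis	Chr06:112308032..112310368(-)	2337	2250	9	0
Tr13	tropicalis	Chr02:162067553..162069883(-)	2331	2331	0	0
Tr14	tropicalis	scaffold_51:231432..233759(-)	2328	2328	5	0
Tr15	tropicalis	Chr01:83498100..83500424(+)	2325	2325	5	0
Tr16	tropicalis	Chr04:108160710..108163031(-)	2322	2322	0	0
Tr17	tropicalis	Chr09:29639969..29642278(-)	2310	2310	0	0
Tr18	tropicalis	Chr02:66952233..66954539(-)	2307	2307	0	0
Tr19	tropicalis	Chr04:41679747..41682050(+)	2304	2229	0	0
Tr20	tropicalis	scaffold_16:1256554..1258851(+)	2298	2298	4	0
Tr21	tropicalis	Chr04:107657217..107659511(+)	2295	2295	9	0
Tr22	tropicalis	Chr01:168455606..168457900(-)	2295	2295	9	0
Tr23	tropicalis	Chr03:106168762..106171056(-)	2295	2295	9	0
Tr24	tropicalis	scaffold_561:30795..33086(-)	2292	2256	0	0
Tr25	tropicalis	Chr01:107512548..107514821(+)	2274	2274	4	0
Tr26	tropicalis	Chr09:13318232..13320439(-)	2208	2208	0	0
Tr27	tropicalis	scaffold_4830:88..2292(-)	2205	2205	5	0
Tr28	tropicalis	Chr04:128881775..128883943(-)	2169	2169	0	0
Tr29	tropicalis	Chr04:128872195..128874363(-)	2169	2169	0	0
Tr30	tropicalis	Chr09:10540280..10542436(+)	2157	2157	0	0
Tr31	tropicalis	Chr09:10547870..10549993(+)	2124	2091	0	0
Tr32	tropicalis	Chr03:80573408..80575504(+)	2097	2097	0	0
Tr33	tropicalis	Chr09:10557320..10559413(+)	2094	2094	1	1
Tr34	tropicalis	scaffold_731:1892..3937(-)	2046	2046	0	0
Tr35	tropicalis	Chr05:37113502..37115535(-)	2034	2034	3	0
Tr36	tropicalis	scaffold_161:120530..122407(+)	1878	1878	8	0
Tr37	tropicalis	Chr01:130854739..130856610(-)	1872	1872	0	0
Tr38	tropicalis	Chr09:29654976..29656787(-)	1812	1812	0	0
Lv1	laevis	chr9_10L:117582522..117585011(-)	2490	2433	4	0
Lv2	laevis	chr6S:1512718..1515198(-)	2481	2481	1	1
Lv3	laevis	chr1L:4995471..4997924(-)	2454	2454	4	0
Lv4	laevis	chr8L:50116481..50118844(+)	2364	2292	0	0
Lv5	laevis	Scaffold261:26626..28977(+)	2352	2352	0	0
Lv6	laevis	chr8L:99349197..99351548(-)	2352	2352	2	0
Lv7	laevis	chr2L:167641114..167643453(-)	2340	2340	0	0
Lv8	laevis	chr2S:147754724..147757057(-)	2334	2334	0	0
Lv9	laevis	chr9_10L:77656066..77658378(+)	2313	2313	0	0
Lv10	laevis	chr4S:91247377..91249686(-)	2310	2310	1	1
Lv11	laevis	chr4S:1463674..1465929(-)	2256	2217	1	1
Lv12	laevis	chr3L:58143401..58145647(+)	2247	2211	0	0
Lv13	laevis	chr9_10L:110876140..110878383(-)	2244	2244	0	0
Lv14	laevis	chr4L:133759875..133762109(+)	2235	2187	0	0
Lv15	laevis	chr4S:20852192..20854426(-)	2235	2235	0	0
Lv16	laevis	chr4L:26594086..26596320(+)	2235	2235	1	1
Lv17	laevis	chr4S:1470489..1472717(-)	2229	2229	2	1
Lv18	laevis	chr6L:145404209..145406428(-)	2220	2220	0	0
Lv19	laevis	chr9_10L:110897783..110899978(-)	2196	2196	0	0
Lv20	laevis	chr4S:112529046..112531238(-)	2193	2193	0	0
Lv21	laevis	chr4S:112539344..112541533(-)	2190	2190	0	0
Lv22	laevis	chr4L:133769461..133771647(+)	2187	2187	0	0
Lv23	laevis	Scaffold22:1796503..1798647(-)	2145	2145	3	0
Lv24	laevis	chr4L:26633802..26635940(+)	2139	2103	0	0
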