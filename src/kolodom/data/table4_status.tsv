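name	species	nt_subs	nt_gap	aa_subs	dnds	status
Tr1	tropicalis	20	6	10	0.396	active?
Tr2	tropicalis	112	4	frame-shift	-	active?
Tr3	tropicalis	5	0	3	1.006	domestication?
Tr4	tropicalis	11	12	7	0.501	ancient domestication
Tr5	tropicalis				 	currently active
Tr6	tropicalis	1	0	1	dS = 0	currently active
Tr7	tropicalis	9	0	7	0.696	currently active
Tr8	tropicalis	26	0	21	1.057	currently active
Tr9	tropicalis					currently active
Tr10	tropicalis	5	0	1	0.084	ancient domestication
Tr11	tropicalis					currently active
Tr12	tropicalis	205	991	frame-shift	-	active?
Tr13	tropicalis	26	0	8	0.173	ancient domestication
Tr14	tropicalis					currently active
Tr15	tropicalis	0	3	0	dS = 0	currently active
Tr16	tropicalis	3	0	2	0.527	ancient domestication
Tr17	tropicalis	24	0	13	0.434	domestication?
Tr18	tropicalis	15	0	9	0.504	domestication?
Tr19	tropicalis	4	30	4	dS = 0	ancient domestication
Tr20	tropicalis	53	0	29	0.403	currently active
Tr21	tropicalis					currently active
Tr22	tropicalis	0	0	0	dS = 0	currently active
Tr23	tropicalis					currently active
Tr24	tropicalis	57	6	23	0.28	domestication?
Tr25	tropicalis					active?
Tr26	tropicalis	15	0	3	0.058	domestication?
Tr27	tropicalis	55	0	19	0.118	active?
Tr28	tropicalis	9	0	6	0.629	ancient domestication
Tr29	tropicalis	27	0	12	0.312	ancient domestication
Tr30	tropicalis	5	0	2	0.328	ancient domestication
Tr31	tropicalis	21	3	11	0.359	ancient domestication
Tr32	tropicalis	7	0	6	1.444	domestication?
Tr33	tropicalis	30	0	8	0.14	ancient domestication
Tr34	tropicalis	23	0	9	0.192	domestication?
Tr35	tropicalis					active?
Tr36	tropicalis					active?
Tr37	tropicalis					domestication?
Tr38	tropicalis	12	0	5	0.196	domestication?
Lv1	laevis					currently active
Lv2	laevis	466	237	202	0.285	domestication?
Lv3	laevis	472	63	210	0.194	currently active
Lv4	laevis	263	6	110	0.257	ancient domestication
Lv5	laevis					domestication?
Lv6	laevis					currently active
Lv7	laevis	289	51	140	0.391	ancient domestication
Lv8	laevis	293	57	141	0.301	ancient domestication
Lv9	laevis	303	42	154	0.341	ancient domestication
Lv10	laevis	302	36	161	0.463	ancient domestication
Lv11	laevis	335	42	172	0.358	ancient domestication
Lv12	laevis	546	252	213	0.100	domestication?
Lv13	laevis	359	198	164	0.365	ancient domestication
Lv14	laevis	305	36	155	0.413	ancient domestication
Lv15	laevis	411	393	157	0.195	domestication?
Lv16	laevis	305	36	162	0.349	ancient domestication
Lv17	laevis	331	54	162	0.336	ancient domestication
Lv18	laevis					domestication?
Lv19	laevis	335	69	156	0.328	ancient domestication
Lv20	laevis	323	66	165	0.497	ancient domestication
Lv21	laevis	312	33	166	0.472	ancient domestication
Lv22	laevis	356	72	193	0.521	ancient domestication
Lv23	laevis	591	294	240	0.153	active?
Lv24	laevis					domestication?
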