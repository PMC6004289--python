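cluster_id	shape	synteny_ok	members
D1	triplet	1	Tr13,Lv7,Lv8
D2	triplet	1	Tr19,Lv16,Lv11,Lv17
D3-1	triplet	1	Tr28,Lv22,Lv20
D3-2	triplet	1	Tr29,Lv14,Lv21
D4	doublet	1	Tr16,Lv10
D5	doublet	1	Tr10,Lv4
D6-1	doublet	1	Tr30,Tr31,Lv19
D6-2	doublet	1	Tr33,Lv13
D7	doublet	1	Tr4,Lv9
D8	doublet	0	Tr32,Lv12
D9	doublet	0	Tr34,Lv15
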