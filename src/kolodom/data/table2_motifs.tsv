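name	species	dde	h2ch	c2ch	pwf	avptif	flag
Tr1	tropicalis	DDE	HHCH	CCCH	PWF	SIPTQF
Tr2	tropicalis	DDE	HHCH	YCCH	PWF	AIPSVF
Tr3	tropicalis	DGD	HHCH	--CP	PLL	ALQ-LM
Tr4	tropicalis	DNK	HHCQ	CCCH	PWF	ATPTLF
Tr5	tropicalis	DDE	HHCH	CCCH	PWF	AVPTIF	++
Tr6	tropicalis	DDE	HHCH	CCCH	PWF	AVPTIF	++
Tr7	tropicalis	DDE	HHCH	CCCH	PWF	AVPTIF	++
Tr8	tropicalis	DDE	HHCH	CCCH	PWF	AVPTIF	++
Tr9	tropicalis	DDE	HHCH	CCCH	PWF	AVPTIF	++
Tr10	tropicalis	DDE	HHCH	CCCH	PWF	AVPTIF	++
Tr11	tropicalis	DDE	HHCH	CCCH	PWF	AVPTIF	++
Tr12	tropicalis	DDE	HHCH	CCCH	PWF	ATPTSF
Tr13	tropicalis	DDE	HHCH	CCCH	PWF	AIPTLF	+
Tr14	tropicalis	DDE	HHCH	CCCH	PWF	AIPTLF	+
Tr15	tropicalis	DDE	HHCH	CCCH	PWF	AIPTLF	+
Tr16	tropicalis	DDK	HHCH	CCCH	PWF	AIPTIF
Tr17	tropicalis	DED	HHCH	CCCH	PWF	AVPTQF
Tr18	tropicalis	DDE	HHCH	CCCH	PWF	AVPTVF	+
Tr19	tropicalis	DGE	HHCH	CCCH	PWF	AVPTIF
Tr20	tropicalis	DDE	HHCH	CCCH	PWF	AVPTIF	++
Tr21	tropicalis	DDE	HHCH	CCCH	PWF	AVPTLF	+
Tr22	tropicalis	DDE	HHCH	CCCH	PWF	AVPTLF	+
Tr23	tropicalis	DDE	HHCH	CCCH	PWF	AVPTLF	+
Tr24	tropicalis	DDE	HHCH	CCCH	PWF	AVPTIF	++
Tr25	tropicalis	DDE	HHCH	-VCH	PWF	AVPTIF
Tr26	tropicalis	DDV	HHCH	CCCH	PWF	AVPTIF
Tr27	tropicalis	DDE	HHCH	CCCH	PWF	AMPTQF
Tr28	tropicalis	GDE	HHCH	CCCH	PWF	AVPTIF
Tr29	tropicalis	GNE	HHCH	CCCH	PWF	AVPTIF
Tr30	tropicalis	DDL	HHCH	CCCH	PWF	AVPTIF
Tr31	tropicalis	DDL	HHCH	CCCH	PWF	AVPTIF
Tr32	tropicalis	DDE	HHCH	CCCH	PWF	AVPTIF	++
Tr33	tropicalis	NDT	HDCN	CCCH	PWF	ALPTIF
Tr34	tropicalis	DEE	HHCH	--T-	P--	TEPVVV
Tr35	tropicalis	DDE	HHCH	S-C-	P--	------
Tr36	tropicalis	DD-	HHCH	CCCH	PWF	AVPTIY
Tr37	tropicalis	DDE	YHCH	-SC-	S-F	---T--
Tr38	tropicalis	DED	HHCH	Y-CK	--L	SLSTLL
Lv1	laevis	DDE	HHCH	CCCH	PWF	AVPSIF	+
Lv2	laevis	DED	HHCH	CCCH	PWF	AVPTLF
Lv3	laevis	DDE	HHCH	CCCH	PWF	AIPSIF	+
Lv4	laevis	DDE	HHCH	CCCH	PWF	AIPTIF	+
Lv5	laevis	DDK	HHCH	CCCH	PWF	AFPTLF
Lv6	laevis	DDE	HHCH	CCCH	PWF	AVPTIF	++
Lv7	laevis	DDE	HHCH	CCCH	PWF	AVPTIF	++
Lv8	laevis	DDE	HHCH	CCCH	PWF	AVPTIF	++
Lv9	laevis	DNK	RHCH	CCCH	PWF	ATPTLF
Lv10	laevis	HDN	HHCH	CCCH	PWF	AIPTIF
Lv11	laevis	DDQ	HHCH	CCCH	PWF	AVPTIF
Lv12	laevis	YNE	HHCH	CCCH	PWF	AVPTIF
Lv13	laevis	DDK	HNCH	CCCH	PWF	ALPSIF
Lv14	laevis	GDE	HHCH	CCCH	PWF	AVPTIF
Lv15	laevis	DEE	HHCH	CCCH	PWF	AIPTIF
Lv16	laevis	DSE	HHCH	CCCH	PWF	AVPTIF
Lv17	laevis	DDQ	HHCH	CCCH	PWF	AVPTIF
Lv18	laevis	DDE	HHCH	CCCH	PWF	AVPTVF	+
Lv19	laevis	DDL	HHCH	CCCH	PWF	AVPTIF
Lv20	laevis	GDE	HHCH	CCCH	PWF	AVPTIF
Lv21	laevis	GDE	HHCH	CCCH	PWF	AVPTIF
Lv22	laevis	GDE	HHCH	CCCH	PWF	AIPTIF
Lv23	laevis	DDP	HHCH	CCCH	PWF	AVPTLF
Lv24	laevis	DDK	HHCH	CCCH	PWF	AVPTIF
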