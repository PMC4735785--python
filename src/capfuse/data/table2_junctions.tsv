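Sample	Left_chr	Left_str	Left_breakpoint	Gene_left	Right_chr	Right_str	Right_breakpoint	Gene_right	Mode	Right_breakpoint_corrected
SCMC-000206	chr12	F	12,023,837	ETV6	chr21	R	36,315,905	RUNX1	c
SCMC-000206	chr5	F	5,923,540	KIAA0947 (dist=433,096); FLJ33360 (dist=387,013)	chr12	F	12,023,848	ETV6
SCMC-000206	chr21	R	36,315,676	RUNX1	chr5	F	5,684,751	KIAA0947 (dist=194,403); FLJ33360 (dist=625,705)
SCMC-000452	chr12	F	12,032,593	ETV6	chr21	R	36,275,614	RUNX1	c
SCMC-000452	chr12	R	12,032,602	ETV6	chr21	F	36,275,819	RUNX1	d
SCMC-000479	chr12	R	12,033,450	ETV6	chr21	F	36,266,210	RUNX1	d
SCMC-000479	chr12	R	12,029,669	ETV6	chr21	R	36,266,328	RUNX1	b
SCMC-000862	chr12	F	12,027,788	ETV6	chr21	R	36,326,005	RUNX1	c
SCMC-000862	chr12	R	12,026,106	ETV6	chr21	F	36,325,404	RUNX1	d
SCMC-000863	chr12	F	12,023,597	ETV6	chr21	R	36,275,255	RUNX1	c
SCMC-000863	chr5	R	36,122,247	LMBRD2	chr21	F	36,275,263	RUNX1
SCMC-000863	chr5	F	36,122,307	LMBRD2	chr12	F	12,023,436	ETV6
SCMC-000864	chr12	F	12,035,255	ETV6	chr21	R	36,416,976	RUNX1	c
SCMC-000867	chr12	F	12,035,516	ETV6	chr21	R	36,281,679	RUNX1	c
SCMC-000926	chr12	F	12,023,822	ETV6	chr21	R	362,65,359	RUNX1	c
SCMC-000926	chr12	R	12,023,685	ETV6	chr21	F	37,500,446	LOC100133286 (dist=1503); CBR3-AS1 (dist=3548)	d
SCMC-000966	chr12	F	12,031,429	ETV6	chr21	R	36,411,881	RUNX1	c
SCMC-000966	chr6	F	79,662,190	PHIP	chr21	F	36,414,387	RUNX1
SCMC-000966	chr6	R	132,835,666	STX7 (dist=1322); TAAR9 (dist=23,663)	chr12	F	12,031,621	ETV6
SCMC-001031	chr12	F	12,036,660	ETV6	chr21	R	36,262,972	RUNX1	c
SCMC-001031	chr12	R	12,036,598	ETV6	chr21	F	36,263,015	RUNX1	d
SCMC-001108	chr12	F	120,28,006	ETV6	chr21	R	36,402,216	RUNX1	c
SCMC-001108	chr12	R	12,028,066	ETV6	chr21	F	36,402,001	RUNX1	d
SCMC-001213	chr12	F	120,34,768	ETV6	chr21	R	36,289,889	RUNX1	c
SCMC-001213	chr12	R	8,174,744	SLC2A3 (dist=85,795); FOXJ2 (dist=10,558)	chr21	F	36,289,801	RUNX1	d
SCMC-001222	chr12	F	120,35,760	ETV6	chr21	R	36,309,078	RUNX1	c
SCMC-001222	chr12	R	12,046,241	ETV6	chr21	F	36,309,775	RUNX1	d
SCMC-001224	chr12	F	12,029,780	ETV6	chr21	R	36,363,476	RUNX1	c
SCMC-001224	chr12	R	12,029,781	ETV6	chr21	F	36,363,464	RUNX1	d
SCMC-001245	chr12	F	12,036,973	ETV6	chr21	R	36,283,393	RUNX1	c
SCMC-001245	chr8	F	26,466,011	DPYSL2	chr12	F	12,037,354	ETV6
SCMC-001245	chr8	R	29,723,210	LOC286135 (dist=55,819)	chr21	F	36,283,600	RUNX1
SCMC-001384	chr12	R	12,036,313	ETV6	chr21	F	36,292,336	RUNX1	d
SCMC-001388	chr12	F	12,032,965	ETV6	chr21	R	36,308,543	RUNX1	c
SCMC-001388	chr12	R	12,033,033	ETV6	chr21	F	36,308,464	RUNX1	d
SCMC-001434	chr12	F	12,031,547	ETV6	chr21	R	36,358,156	RUNX1	c
SCMC-001437	chr12	R	12,035,361	ETV6	chr21	F	36,264,128	RUNX1	d
SCMC-001443	chr12	F	12,029,090	ETV6	chr21	R	36,327,209	RUNX1	c
SCMC-001443	chr12	R	12,029,101	ETV6	chr21	F	36,328,064	RUNX1	d
SCMC-001478	chr12	F	12,029,274	ETV6	chr21	R	36,357,909	RUNX1	c
SCMC-001478	chr12	R	12,029,278	ETV6	chr21	F	36,357,982	RUNX1	d
SCMC-001511	chr12	F	12,029,759	ETV6	chr21	R	36,400,256	RUNX1	c
SCMC-001511	chr12	R	12,029,760	ETV6	chr21	F	36,400,256	RUNX1	d
SCMC-001579	chr12	F	12,029,886	ETV6	chr21	R	38,264,151	RUNX1	c	36,264,151
SCMC-001579	chr15	F	86,092,449	AKAP13	chr21	F	36,264,161	RUNX1
SCMC-001579	chr15	R	86,092,248	AKAP13	chr12	F	12,029,986	ETV6
SCMC-001580	chr12	F	12,027,748	ETV6	chr21	R	36,261,050	RUNX1	c
SCMC-001644	chr12	F	12,031,966	ETV6	chr21	R	36,259,665	RUNX1	c
SCMC-001644	chr12	R	12,031,976	ETV6	chr21	F	36,259,758	RUNX1	d
SCMC-001645	chr12	F	12,023,103	ETV6	chr21	R	36,264,307	RUNX1	c
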