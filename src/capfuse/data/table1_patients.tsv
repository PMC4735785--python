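POND_id	Gender	Age_years	WBC_1e9_L	FAB	Blast_ratio_pct	Immunophenotype	Fusion_gene	Karyotype	Relapse_site	Outcome	Remission_days
SCMC-000206	Male	4.6	158	ALL-L2	90.4	B	ETV6-RUNX1	ND	BM; CNS	Relapse	1297
SCMC-000452	Male	3.2	50.2	ALL-L3	98.4	B	ETV6-RUNX1	ND		Alive	1917
SCMC-000479	Female	6.8	67.6	ALL-L3	90	B	ETV6-RUNX1	ND		Alive	1807
SCMC-000862	Female	1.9	70.2	ALL-L2	98	B	ETV6-RUNX1	46,XX		Alive	1594
SCMC-000863	Male	3.1	7.4	ALL-L2	97.2	B	ETV6-RUNX1	46,XY	CNS; BM	Relapse	1319
SCMC-000864	Male	5.8	5.1	ALL-L2	75.5	B	ETV6-RUNX1	46,XY,del(6)(q14q22)/46,XY		Alive	1581
SCMC-000867	Male	4.3	4.3	ALL-L1	97.6	B	ETV6-RUNX1	46,XY		Alive	1576
SCMC-000926	Male	6.7	119.8	ALL-L2	95.2	B	ETV6-RUNX1	ND		Alive	1449
SCMC-000966	Male	3.9	27.3	ALL-L2	98.4	B	ETV6-RUNX1	45,XY,-6,-20,+der(21)t(6;21)(p21;p12)	BM	Relapse	428
SCMC-001031	Male	13	1.9	ALL-L3	89.6	B	ETV6-RUNX1	46,XY		Alive	1301
SCMC-001108	Female	4.8	3.8	ALL-L2	97.6	B	ETV6-RUNX1	46,XX		Alive	1122
SCMC-001213	Female	2.8	3.6	ALL-L3	94.8	B	ETV6-RUNX1	46,XX		Alive	1057
SCMC-001222	Male	2.4	15	ALL-L2	97.2	B	ETV6-RUNX1	46,XY		Alive	1033
SCMC-001224	Male	6	3.6	ALL-L2	87.6	B	ETV6-RUNX1	46,XY		Alive	1034
SCMC-001245	Male	5.4	15	ALL-L2	92.8	B	ETV6-RUNX1	46,XY	BM	Relapse	546
SCMC-001384	Male	5.9	14.2	ALL-L3	96.4	B	ETV6-RUNX1	47,XY,+21		Alive	586
SCMC-001388	Female	3.9	4	ALL-L2	92.8	B	ETV6-RUNX1	ND		Alive	557
SCMC-001434	Male	3.8	3.6	ALL-L2	96.8	B	ETV6-RUNX1	ND		Alive	463
SCMC-001437	Male	2.3	9.5	ALL-L2	91.2	B	ETV6-RUNX1	46,XY		Alive	471
SCMC-001443	Male	6.1	3.8	ALL-L3	92	B	ETV6-RUNX1	46,XY		Alive	466
SCMC-001478	Female	5.3	3.2	ALL-L2	93.2	B	ETV6-RUNX1	ND		Alive	173
SCMC-001511	Male	4.2	4.2	ALL-L2	99.2	B	ETV6-RUNX1	46,XY		Alive	350
SCMC-001579	Male	7.4	31	ALL-L3	95.6	B	ETV6-RUNX1	46,XY		Alive	180
SCMC-001580	Male	6.7	5.4	ALL-L2	95.6	B	ETV6-RUNX1	47,XY,+8/46,XY		Alive	118
SCMC-001644	Male	9	2.7	ALL-L3	94.8	B	ETV6-RUNX1	ND		Alive	174
SCMC-001645	Male	3	5.3	ALL-L3	93.2	B	ETV6-RUNX1	ND		Alive	173
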