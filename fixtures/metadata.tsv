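sample_id	group	stage	replicate	peat_axis	TN	NH4	NO3	AP	AK	TS	pH	moisture	OM	density	unit_weight
CT0_s1_r1	0	1	1	-0.44408810384879555	0.0	0.0	11.271790691992775	14.273042931587428	89.21891978276545	0.0	8.377318345446561	6.115454820319107	0.0	2.957754490902597	1.5832304381155236
CT0_s1_r2	0	1	2	-0.48453723929269255	0.0	0.0	12.940913103445729	12.966951035344424	101.01142843794997	0.0	8.280594599040842	7.610036273673592	0.0	2.9912051064054577	1.6145155485360938
CT0_s2_r1	0	2	1	-0.09758344879079403	1.5707830205178854	2.548797069460882	11.621109771969623	18.221944524738028	142.3711756522655	0.8098705608874446	7.895197180521559	24.860790467896155	0.0	2.716958748773175	1.3792031057983138
CT0_s2_r2	0	2	2	-0.02362952334015181	0.6337542049544841	6.47679999149551	11.399906860057854	18.857853218232194	140.9298704151853	0.7567762245367311	7.830345970049011	32.84404059794802	0.0	2.6575490107729354	1.2730853929970793
CT0_s3_r1	0	3	1	0.4873094077765306	3.810654449780041	19.79327795315685	12.798806436696069	27.065008514516446	212.52507806844534	2.014368066115502	7.227351712332047	53.32437498384917	108.38842046707347	2.401301602984945	0.9874513264022426
CT0_s3_r2	0	3	2	0.5439237488605975	5.536330437210687	23.112879250217215	12.450241799859228	28.44139151201275	210.83714377089132	2.1809316933786786	7.126991874476582	58.4459948832052	138.3294830446337	2.333238067308032	0.915808914702027
CT100_s1_r1	100	1	1	0.5829657387673162	5.586037832921087	28.74057926312486	12.354675760445089	28.491157480372344	220.10897170891764	2.035729867890908	7.093462781234137	55.6759061110874	139.71494739894393	2.31089812790088	0.9264239022760318
CT100_s1_r2	100	1	2	0.4636816302912522	4.639366598310181	21.291531876960168	11.591955977930928	26.623040559667952	192.03770314580228	1.7834190782546122	7.311916398079844	49.34619630918067	129.92154302925238	2.3898652376107314	1.0149220845800018
CT100_s2_r1	100	2	1	1.0451659816464565	9.01344375504422	41.088780851420324	12.43384852477587	35.30240857508582	280.0677958086999	3.3977735399812405	6.4624978477830055	76.87797896137023	231.94996120853395	1.9239505020841612	0.5896313567741904
CT100_s2_r2	100	2	2	0.962994910035027	8.648198946983936	35.558895327212284	12.07740680143014	35.101433294891244	257.7438708970469	3.2214524364176014	6.735795917968402	74.16614462485308	229.4604917359753	2.033112145409554	0.6432645478980613
CT100_s3_r1	100	3	1	1.4897991510163735	11.273189096406014	55.58914039428185	11.754106519261706	43.00438274720113	313.72108653823886	4.291150639351523	6.006802587554055	94.36593185306907	329.609074414543	1.7630749807498616	0.36350283186651083
CT100_s3_r2	100	3	2	1.5255749864905004	12.599882200605503	59.75334654198505	11.33150368203998	42.763503523539285	316.95380404997394	4.5496887892620865	5.974318640484009	98.48258474291548	363.2039674666017	1.7205290788808028	0.3448251790727057
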