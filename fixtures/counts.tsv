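sample_id	OTU_1	OTU_2	OTU_3	OTU_4	OTU_5	OTU_6	OTU_7	OTU_8	OTU_9	OTU_10	OTU_11	OTU_12	OTU_13	OTU_14	OTU_15	OTU_16	OTU_17	OTU_18	OTU_19	OTU_20	OTU_21	OTU_22	OTU_23	OTU_24	OTU_25	OTU_26	OTU_27	OTU_28	OTU_29	OTU_30	OTU_31	OTU_32	OTU_33	OTU_34	OTU_35	OTU_36	OTU_37	OTU_38	OTU_39	OTU_40	OTU_41	OTU_42	OTU_43	OTU_44	OTU_45	OTU_46	OTU_47	OTU_48	OTU_49	OTU_50	OTU_51	OTU_52	OTU_53	OTU_54	OTU_55	OTU_56	OTU_57	OTU_58	OTU_59	OTU_60
CT0_s1_r1	0	0	0	0	0	0	0	10	0	0	0	0	0	1	0	0	0	1	0	0	0	1	0	0	0	0	32	0	0	0	0	0	0	0	0	0	0	2	0	0	0	0	1929	0	0	0	24	0	0	0	0	0	0	0	0	0	0	0	0	0
CT0_s1_r2	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	18	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1964	0	0	0	15	0	0	0	0	0	0	0	0	0	0	0	0	0
CT0_s2_r1	2	1	0	1	0	0	0	231	0	0	0	0	0	129	0	63	0	94	0	0	0	34	0	3	0	0	417	254	0	0	0	0	5	0	0	0	25	113	0	0	0	0	254	0	0	0	350	0	0	0	0	0	0	0	0	24	0	0	0	0
CT0_s2_r2	8	0	0	15	0	0	0	250	0	0	0	0	0	185	0	108	0	128	0	0	0	55	0	1	0	0	285	254	0	0	0	0	32	1	0	10	66	155	0	0	0	0	81	0	0	0	313	0	0	0	0	0	0	0	0	51	2	0	0	0
CT0_s3_r1	47	83	4	38	11	14	0	0	0	82	9	0	76	2	84	4	0	1	89	1	3	2	92	70	18	94	1	0	81	84	37	70	13	88	23	26	11	0	103	81	0	101	0	89	6	0	0	1	0	6	73	0	83	2	16	8	65	21	81	6
CT0_s3_r2	30	58	5	15	26	38	0	0	4	80	7	0	62	0	92	2	1	0	75	3	10	2	95	30	32	86	0	0	77	71	75	89	6	79	47	13	5	0	76	99	0	82	0	69	21	0	0	1	2	14	74	0	81	14	32	4	69	33	97	17
CT100_s1_r1	12	66	10	8	44	64	0	0	10	80	21	0	55	0	73	0	3	0	54	9	19	0	81	17	45	68	0	0	91	76	87	100	4	51	44	5	0	0	83	88	4	53	0	67	20	0	0	4	5	41	52	0	81	20	52	0	47	57	93	36
CT100_s1_r2	62	90	0	44	8	14	0	0	0	67	3	0	88	5	82	9	0	1	95	1	3	11	78	81	12	79	0	0	52	83	34	45	35	83	20	41	16	2	89	79	1	96	0	87	3	0	0	0	0	6	105	0	85	1	13	11	80	16	79	5
CT100_s2_r1	0	0	87	0	24	12	54	0	127	0	53	252	0	0	0	0	155	0	0	111	62	0	0	0	7	1	0	0	0	0	2	0	0	0	8	0	0	0	0	0	199	0	0	0	27	159	0	151	140	19	0	246	0	47	13	0	0	7	0	37
CT100_s2_r2	0	1	126	0	44	31	13	0	170	0	116	128	0	0	1	0	159	0	0	140	88	0	0	0	33	0	0	0	1	0	8	1	0	0	13	0	0	0	0	0	172	1	0	0	58	41	0	169	155	56	0	81	0	81	28	0	0	27	2	56
CT100_s3_r1	0	0	0	0	0	0	1482	0	0	0	0	55	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	353	0	0	0	0	0	109	0	0	0	0	0	0	0	0
CT100_s3_r2	0	0	0	0	0	0	1527	0	0	0	0	48	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	346	0	0	0	0	0	79	0	0	0	0	0	0	0	0
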