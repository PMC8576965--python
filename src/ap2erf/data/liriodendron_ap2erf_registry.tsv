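# AP2/ERF gene registry for Liriodendron chinense: 104 family members with
# protein length (aa), intron count and Nakano-style group label.
# Digit fields were disambiguated against the in-text anchors (length range
# 100-758 aa, AP2-subfamily introns 6-12, stated per-group member counts).
name	gene_id	scaffold	protein_length	intron_count	group
LcERF1	Unigene40981_All	Scaffold211	261	0	I
LcERF2	Lchi03057	Scaffold506	328	1	I
LcERF3	Lchi07965	Scaffold708	325	1	I
LcERF4	Lchi07966	Scaffold708	561	2	I
LcERF5	Lchi22931	Scaffold1519	432	1	I
LcERF6	Lchi09796	Scaffold2048	316	1	I
LcERF7	Lchi16995	Scaffold3097	316	0	I
LcERF8	Lchi23250	Scaffold142	152	0	II
LcERF9	Lchi16170	Scaffold408	193	1	II
LcERF10	Unigene12650_All	Scaffold416	188	0	II
LcERF11	Lchi16911	Scaffold480	199	1	II
LcERF12	Unigene40401_All	Scaffold525	185	0	II
LcERF13	Unigene20830_All	Scaffold836	186	0	II
LcERF14	Lchi11957	Scaffold345	224	1	III
LcERF15	Lchi04946	Scaffold530	235	1	III
LcERF16	Lchi04947	Scaffold530	295	1	III
LcERF17	CL2522.Contig2_All	Scaffold530	223	0	III
LcERF18	CL10877.Contig3_All	Scaffold530	223	0	III
LcERF19	Unigene6126_All	Scaffold530	211	0	III
LcERF20	Lchi33109	Scaffold1203	229	1	III
LcERF21	Lchi33111	Scaffold1203	227	1	III
LcERF22	Lchi34895	Scaffold1374	513	4	III
LcERF23	Lchi29925	Scaffold1675	425	3	III
LcERF24	Lchi08587	Scaffold39	420	1	III
LcERF25	CL5589.Contig2_All	Scaffold345	203	0	III
LcERF26	Unigene11386_All	Scaffold432	211	0	III
LcERF27	CL5589.Contig1_All	Scaffold530	246	0	III
LcERF28	Lchi00950	Scaffold723	217	0	III
LcERF29	Lchi01616	Scaffold1191	100	1	III
LcERF30	Unigene5530_All	Scaffold1191	252	0	III
LcERF31	Lchi32377	Scaffold1289	210	0	III
LcERF32	Lchi26370	Scaffold1364	193	1	III
LcERF33	Lchi08922	Scaffold3419	244	0	III
LcERF34	Lchi28169	Scaffold654	418	1	IV
LcERF35	Lchi23878	Scaffold1043	141	0	IV
LcERF36	Lchi22387	Scaffold1263	229	1	IV
LcERF37	Lchi13652	Scaffold1315	429	1	IV
LcERF38	Lchi30363	Scaffold2365	475	3	IV
LcERF39	Lchi30365	Scaffold2365	354	1	IV
LcERF40	Lchi31374	Scaffold3032	404	1	IV
LcERF41	Lchi34724	Scaffold3708	355	1	IV
LcERF42	Lchi10868	Scaffold159	758	2	V
LcERF43	Lchi11945	Scaffold345	421	7	V
LcERF44	Lchi25937	Scaffold1371	183	1	V
LcERF45	Lchi16637	Scaffold2432	226	1	V
LcERF46	Lchi34468	Scaffold2926	206	1	V
LcERF47	Lchi05084	Scaffold3476	136	1	V
LcERF48	Lchi07311	Scaffold172	268	0	VI
LcERF49	Lchi22103	Scaffold920	369	2	VI
LcERF50	Lchi17039	Scaffold3097	359	1	VI
LcERF51	Lchi02638	Scaffold416	310	1	VII
LcERF52	Lchi02639	Scaffold416	362	1	VII
LcERF53	Lchi11452	Scaffold525	383	1	VII
LcERF54	Lchi04620	Scaffold775	290	1	VII
LcERF55	Lchi04621	Scaffold775	289	1	VII
LcERF56	Lchi04623	Scaffold775	236	1	VII
LcERF57	Lchi07083	Scaffold135	273	1	VIII
LcERF58	Lchi07084	Scaffold135	203	0	VIII
LcERF59	Lchi13371	Scaffold1075	207	1	VIII
LcERF60	Lchi11824	Scaffold1130	375	3	VIII
LcERF61	Lchi13392	Scaffold1763	207	1	VIII
LcERF62	Unigene7795_All	Scaffold1763	205	0	VIII
LcERF63	Lchi31572	Scaffold1784	180	1	VIII
LcERF64	Lchi08484	Scaffold39	204	1	IX
LcERF65	Lchi09908	Scaffold79	316	1	IX
LcERF66	Unigene24905_All	Scaffold79	170	0	IX
LcERF67	Lchi01406	Scaffold432	211	1	IX
LcERF68	Unigene35921_All	Scaffold432	301	0	IX
LcERF69	Lchi08172	Scaffold580	324	0	IX
LcERF70	Lchi07909	Scaffold708	174	1	IX
LcERF71	Lchi31530	Scaffold803	105	2	IX
LcERF72	CL9762.Contig1_All	Scaffold1024	307	0	IX
LcERF73	Lchi05992	Scaffold1024	250	1	IX
LcERF74	Lchi05993	Scaffold1024	350	2	IX
LcERF75	Lchi26525	Scaffold1934	272	1	IX
LcERF76	Lchi26532	Scaffold1934	361	3	IX
LcERF77	Lchi28702	Scaffold54	309	2	X
LcERF78	Unigene10666_All	Scaffold100	235	1	X
LcERF79	Lchi02215	Scaffold682	229	1	X
LcERF80	Lchi02216	Scaffold682	196	1	X
LcERF81	Lchi18461	Scaffold943	403	1	X
LcERF82	Lchi11856	Scaffold1130	128	1	X
LcERF83	Lchi01932	Scaffold1191	292	1	X
LcERF84	Lchi20453	Scaffold1167	328	2	VI-L
LcERF85	Lchi14855	Scaffold41	394	6	AP2
LcERF86	Lchi23120	Scaffold192	405	7	AP2
LcERF87	Lchi16948	Scaffold480	550	9	AP2
LcERF88	Lchi08043	Scaffold502	680	6	AP2
LcERF89	Lchi11241	Scaffold503	375	8	AP2
LcERF90	Lchi28881	Scaffold509	474	7	AP2
LcERF91	Lchi06162	Scaffold527	524	7	AP2
LcERF92	Lchi03252	Scaffold764	535	6	AP2
LcERF93	CL7987.Contig2_All	Scaffold805	572	12	AP2
LcERF94	Unigene5404_All	Scaffold2118	490	6	AP2
LcERF95	Lchi33401	Scaffold2225	563	6	AP2
LcERF96	Lchi13837	Scaffold2467	662	7	AP2
LcERF97	CL6967.Contig2_All	Scaffold2956	327	6	AP2
LcERF98	Unigene39546_All	Scaffold3476	468	7	AP2
LcERF99	Lchi08779	Scaffold67	376	1	RAV
LcERF100	Lchi02516	Scaffold100	607	4	RAV
LcERF101	Lchi02519	Scaffold100	428	2	RAV
LcERF102	Lchi15640	Scaffold1242	354	2	RAV
LcERF103	Lchi23744	Scaffold1330	361	1	RAV
LcERF104	Lchi32356	Scaffold3563	235	5	Soloist
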