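# Pepper (Capsicum annuum) CaDnaJ family catalog: 76 members, chromosome-ordered.
# Unplaced scaffold genes carry chromosome "00" and '.' coordinates.
# Columns: gene_name locus chromosome start end group size_aa mw_da pi introns
gene_name	locus	chromosome	start	end	group	size_aa	mw_da	pi	introns
CaDnaJ01	CA01g16030	1	97618202	97621808	C	574	64187.51	8.54	5
CaDnaJ02	CA01g17770	1	143624907	143627243	C	778	32485.78	6.35	0
CaDnaJ03	CA01g18690	1	156550800	156555986	A	300	32485.78	6.35	11
CaDnaJ04	CA01g22020	1	169879103	169880683	C	526	58220.93	8.34	0
CaDnaJ05	CA01g25030	1	203653187	203656231	C	1014	113869.47	5.73	0
CaDnaJ06	CA01g27370	1	222188570	222189529	C	288	32533.02	8.65	1
CaDnaJ07	CA01g30060	1	252896608	252899637	C	968	110547.4	8.45	2
CaDnaJ08	CA02g03340	2	46401318	46404099	C	469	51784.11	7.97	3
CaDnaJ09	CA02g06030	2	81542166	81542741	C	184	20655.63	8.95	1
CaDnaJ10	CA02g07560	2	109106142	109111419	C	505	57920.91	8.19	4
CaDnaJ11	CA02g15460	2	144816870	144819496	B	352	38501.82	9.17	2
CaDnaJ12	CA03g00750	3	1443148	1444782	C	180	21530.33	9.49	1
CaDnaJ13	CA03g08730	3	28341344	28342355	C	249	28757.26	5.52	1
CaDnaJ14	CA03g19380	3	212945408	212947600	C	730	81652.23	9.02	0
CaDnaJ15	CA03g24080	3	228862136	228863317	C	393	43430.55	9.85	0
CaDnaJ16	CA03g25800	3	235233410	235241868	C	785	59082.25	7.21	9
CaDnaJ17	CA03g31950	3	249441998	249454817	A	421	45593.07	9.23	7
CaDnaJ18	CA03g37040	3	257676539	257678405	C	215	23745.93	5.02	5
CaDnaJ19	CA04g03850	4	11909825	11910715	A	286	31473.8	8.86	1
CaDnaJ20	CA04g12150	4	170393420	170395215	C	209	23712.34	5.97	2
CaDnaJ21	CA04g16150	4	205132799	205133939	C	347	37710.14	8.68	2
CaDnaJ22	CA04g16480	4	205935059	205935586	C	175	20694.67	9.97	0
CaDnaJ23	CA04g19270	4	214481447	214481839	E	130	15006.93	9.52	0
CaDnaJ24	CA04g21880	4	219689981	219690469	C	162	17672.7	9.87	0
CaDnaJ25	CA05g00380	5	478405	487668	C	1432	157852.71	8.6	10
CaDnaJ26	CA05g03820	5	10149653	10153690	A	417	46743.88	6.12	5
CaDnaJ27	CA05g09770	5	104367131	104370250	C	212	23288.3	5.32	5
CaDnaJ28	CA05g10040	5	111541112	111547755	E	258	28711.63	8.68	1
CaDnaJ29	CA05g11830	5	157117370	157119724	C	784	88043.88	7.08	0
CaDnaJ30	CA05g12050	5	165924883	165925699	C	183	20601.3	9.21	2
CaDnaJ31	CA05g17350	5	225414158	225414685	C	175	20366.33	9.6	0
CaDnaJ32	CA05g18040	5	227747673	227748459	C	233	27032.68	6.54	1
CaDnaJ33	CA05g19550	5	231614733	231618044	A	419	46582.74	6.01	4
CaDnaJ34	CA06g00330	6	381222	387261	B	345	39132.52	6.35	9
CaDnaJ35	CA06g19300	6	218954099	218961832	B	345	38203.22	9.11	1
CaDnaJ36	CA06g27020	6	234692516	234693273	D	216	24361.61	9.77	1
CaDnaJ37	CA07g03000	7	13658626	13660185	E	519	57652.71	5.32	0
CaDnaJ38	CA07g04780	7	39783049	39785325	C	758	84482.15	8.38	0
CaDnaJ39	CA07g14410	7	212076067	212082495	B	345	37215.12	9.17	2
CaDnaJ40	CA07g14580	7	212629401	212635278	C	295	33432.67	5.6	8
CaDnaJ41	CA07g20780	7	230038893	230039930	C	138	15577.42	9.69	1
CaDnaJ42	CA07g20790	7	230043861	230044460	C	199	16176.37	8.87	0
CaDnaJ43	CA07g21520	7	231469760	231475634	C	562	64225.13	8.53	8
CaDnaJ44	CA08g04550	8	83124279	83126597	C	772	86114.31	8.13	0
CaDnaJ45	CA08g04600	8	84686555	84694315	C	1272	140416.01	6.06	7
CaDnaJ46	CA08g06460	8	119037486	119039876	B	323	35771.63	8.74	2
CaDnaJ47	CA08g09710	8	127054669	127056621	C	650	74087.37	8.35	0
CaDnaJ48	CA08g11000	8	129804829	129805596	C	255	28904.03	9.37	0
CaDnaJ49	CA08g11250	8	130268529	130271774	C	1081	120431.12	8.59	0
CaDnaJ50	CA08g12000	8	131886063	131888726	C	268	29611.44	6.97	6
CaDnaJ51	CA08g12400	8	132522159	132523390	C	169	19029.27	5.96	4
CaDnaJ52	CA08g15850	8	138087951	138093573	A	447	48202.89	9.29	6
CaDnaJ53	CA08g16300	8	138809830	138812058	E	742	81179.23	8.8	0
CaDnaJ54	CA08g16570	8	139457347	139458186	C	279	31836.41	7.73	0
CaDnaJ55	CA09g01340	9	2706279	2712890	C	666	74144.61	5.07	10
CaDnaJ56	CA09g02890	9	7558262	7563055	C	437	48590.89	6.07	7
CaDnaJ57	CA09g10060	9	137889893	137892146	C	524	57233.33	9.24	4
CaDnaJ58	CA09g11550	9	183732592	183739583	B	344	37544.53	9.23	2
CaDnaJ59	CA10g18490	10	226999515	226999919	C	134	15596.59	9.45	0
CaDnaJ60	CA10g20680	10	230815988	230820272	C	285	32803.76	5.92	7
CaDnaJ61	CA10g21560	10	232003695	232006477	C	303	34356.11	7.71	2
CaDnaJ62	CA11g00780	11	1313193	1320773	C	414	45782.29	5.93	10
CaDnaJ63	CA11g05830	11	31452436	31455481	B	309	34460.23	9.18	1
CaDnaJ64	CA11g10010	11	113882240	113883699	B	355	39775.51	7.59	2
CaDnaJ65	CA11g15800	11	246441094	246443635	A	420	46685.7	5.96	5
CaDnaJ66	CA11g15990	11	246907971	246916099	C	249	29550.83	9.42	8
CaDnaJ67	CA12g07660	12	35330989	35333794	A	420	46676.65	6.17	5
CaDnaJ68	CA12g15900	12	210077200	210078225	C	341	38582.29	8.38	0
CaDnaJ69	CA12g16980	12	217402887	217403441	C	184	20599.06	4.81	0
CaDnaJ70	CA12g18310	12	225521850	225529944	C	366	41110.67	5.41	8
CaDnaJ71	CA12g21480	12	233476472	233477521	C	349	40840.83	7.63	0
CaDnaJ72	CA00g32600	00	.	.	A	421	47162.33	7	6
CaDnaJ73	CA00g54170	00	.	.	E	711	77402.78	5.83	0
CaDnaJ74	CA00g57050	00	.	.	C	193	22938.37	4.56	4
CaDnaJ75	CA00g75210	00	.	.	C	771	86305.23	9.37	0
CaDnaJ76	CA00g93240	00	.	.	C	570	62812.03	4.95	7
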