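gene_id	P01	P02	P03	P04	P05	P06	P07	P08	P09	P10	P11	P12	P13	P14	P15	P16	P17	P18	P19	P20	P21	P22	P23	P24	P25	P26	P27	P28	P29	P30	P31	P32	C01	C02	C03	C04	C05	C06	C07	C08	C09	C10	C11	C12	C13	C14	C15	C16	C17	C18
NONO	19.22617679	21.93252488	5.876674533	34.65520146	7.185058983	26.81558831	132.055447	101.1252879	18.25221945	78.24897777	38.45235358	23.02293728	32.55935015	13.73704698	2.353813474	3.655325801	23.50669813	20.32241572	107.6347412	44.47738303	6.844760205	222.8609442	10.92832205	28.05138308	136.2393834	197.4029857	38.58585049	47.17661495	84.15633665	504.9511447	28.64080227	285.0359343	0.444421341	0.697371833	1.01395948	0.615572207	1.301341855	1.853176124	2.703821666	8.0556444	50.91433496	35.50622311	48.33512274	57.08342524	26.90868529	42.37084513	10.81528666	114.5632091	8.876555777	5.098242509
FCAR	200.8535291	203.6573398	40.9275386	139.5849898	72.50456866	205.0738887	4344.576989	1991.997332	222.0899039	3125.77886	704.2774109	926.0844826	456.6674019	78.24897777	2528762.297	20.32241572	86.52229331	20.96629446	2012.816586	447.2693227	102.1821935	7281.399244	182.278425	922.8804737	2610.300165	10960.30253	436.5490646	1488.867858	1239.033947	4672.56818	266.8712348	6295.040743	0.755236293	0.526680518	0.029769937	2.203810232	0.765778999	3.363585661	5.333194708	10.41073484	319.5726205	363.2955792	223.6346614	256	143.509258	116.5657387	21.85664411	367.0925435	41.78751319	2.496661098
CKAP4	711.6381286	852.1715043	96.00249531	218.2745323	165.995463	544.9575334	5693.105028	2926.579998	455.0874528	1601.269029	2443.951602	932.5259096	861.0779292	176.0693527	82.71058116	48.84029469	639.145241	1789.077291	4938.988862	1443.144453	272.4787667	6338.826214	389.3705608	1413.44497	9184.592511	17991.15266	999.456523	2083.798409	2460.950629	8659.091788	685.0189081	9981.21688	1.140763716	2.531513188	4.377174805	5.296355642	6.844760205	24.00062383	6.498019171	15.03236399	290.0182746	344.8917957	692.1783465	238.8564458	481.0356476	374.8059382	182.9112499	1584.706553	226.7564849	3.237768866
PLEKHO1	0.858565436	1.664397469	0.40332088	2.063366359	0.664342907	0.299369676	7.464263932	0.14309052	0.594603558	0.873572896	3.986161051	1.765405993	1.366040257	0.664342907	0.556710809	0.216134308	1.938579634	0.539614118	0.986232704	0.346277367	0.079384436	2.196185628	1.681792831	0.609205132	4.331900182	1.705269784	0.024433426	2.173469725	1.404444876	0.43077308	0.270743761	0.311002913	0.323088208	0.47963206	0.888842681	1.117287138	0.803850991	1.494849249	1.226884977	0.942784536	1.542210825	0.117034031	0.22298213	2.74156561	3.171136546	0.030395467	0.852634892	0.033377044	1.152686347	4.9588308
BMP6	3.580100284	3.91768119	0.757858283	6.797479993	1.536875181	5.296355642	21.93252488	15.18947394	1.918528239	6.56593287	9.9176616	4.438277888	1.337927555	2.084931522	0.526680518	0.469761375	2.099433367	2.128740365	34.2967508	11.47164198	1.735077374	19.8353232	2.070529848	5.314743256	37.27147477	210.8393004	8.456144324	5.917550037	15.24220797	48.00124766	7.438439541	60.54768939	0.359733395	0.170755032	0.24400794	0.519429552	0.484644908	1.32408891	1.771535038	1.409320755	2.419988178	4.823231311	4.141059695	3.434261746	1.952063522	3.305801273	0.373712312	7.387058486	0.347479555	2.070529848
RNF4	348.4964138	427.5650147	118.6032719	435.0387196	251.6020732	459.8437749	3269.830191	1494.036833	207.2172074	1034.702281	2142.381957	438.0646531	376.1071701	109.8963759	23.10286713	45.72781247	240.5178238	455.0874528	1398.825223	826.0011614	142.0248924	2702.352201	152.7469751	602.5762495	4299.639536	30152.70894	482.7056824	903.8878682	1305.150082	4138.809125	403.101684	4011.705539	1.105730653	1.536875181	1.613283518	4.531535541	1.500038989	6.190259974	2.289448321	10.51954208	197.4029857	188.7064598	120.6764206	19.09337189	83.28587875	109.8963759	30.06472797	30.2738447	58.68825877	68.83164099
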