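No.	Identity	Copy1_Start	Copy1_End	Copy2_Start	Copy2_End	Size	Type
Ra	100.00	150477	152636	323868	326027	2160	DR
Rb	99.87	131028	131822	199473	198679	795	IR
Rc	98.21	47599	48040	387922	387477	446	IR
Rd	99.05	36092	36406	470057	470371	315	DR
Re	89.42	313081	313526	346495	346051	463	IR
Rf	99.14	142655	142886	323014	322783	232	IR
Rg	99.54	262719	262934	336368	336152	217	IR
Rh	86.96	123745	124024	433969	433672	299	IR
Ri	100.00	326022	326181	409770	409929	160	DR
Rj	100.00	110865	111010	215167	215312	146	DR
Rk	98.52	9508	9642	287854	287988	135	DR
Rl	100.00	342433	342559	395427	395301	127	IR
Rm	96.83	144415	144540	176333	176208	126	IR
Rn	99.15	46875	46991	280763	280647	117	IR
Ro	98.25	249100	249213	342464	342575	114	DR
Rp	96.43	346889	346999	359834	359723	112	IR
Rq	98.02	413382	413481	427948	428048	101	DR
Rr	95.33	103082	103184	369910	369804	107	IR
Rs	92.16	15032	15133	214266	214165	102	IR
Rt	86.49	27117	27226	387922	387813	111	IR
Ru	79.86	143849	143965	279630	279773	144	DR
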