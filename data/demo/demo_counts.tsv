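taxon	K1	K2	K3	K4	K5	K6	K7	K8	N1	N2	N3	N4	N5	N6	N7	N8
g__Taxon1	895	1211	640	728	652	1039	442	843	4489	5695	4041	4438	3356	4510	5042	4254
g__Taxon2	2856	3491	3223	2519	2778	2849	3546	2433	9606	8392	6991	7407	12167	9758	9576	7843
g__Taxon3	5175	4083	2365	4534	4204	4734	3111	3670	1125	724	2238	920	1505	2163	2390	2179
g__Taxon4	14	17	6	13	11	11	17	8	7	6	13	10	10	4	26	10
g__Taxon5	13172	11202	11404	12305	13570	10623	12450	16471	6943	9403	9793	11620	7435	8868	7344	8169
g__Taxon6	1614	2763	1566	2104	1584	2834	1292	1701	1873	1705	2198	843	1459	1228	1443	1317
g__Taxon7	1877	1626	1734	2084	2226	1080	2263	1547	1114	796	1083	1386	922	1156	1779	1103
g__Taxon8	4562	5436	8915	5680	4890	7008	6923	3397	4831	3039	3478	3014	3284	2260	2201	5161
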