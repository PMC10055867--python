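metabolite	ct_d4_f2	ct_d4_f1	ct_d14_f2	ct_d14_f1	at_d14_f2	at_d14_f1	os_d14_f2	os_d14_f1	std_f2	std_f1
Leu	752	494	762	484	762	489	772	494	720	540
Leu	950	590	930	584	930	589	934	560	900	600
Leu	900	720	914	720	913	750	910	760	900	720
Leu	1040	610	1073	631	1060	638	1046	608	1080	600
Leu	1040	695	1073	705	1060	709	1046	749	1080	720
Leu	1040	893	1073	923	1060	912	1046	922	1080	900
Leu	2229	611	2210	608	2212	610	2198	620	2220	600
Leu	2170	737	2171	750	2171	752	2163	749	2220	720
Leu	2163	943	2168	943	2157	908	2175	921	2220	900
Ile	1020	540	1020	540	1020	540	1020	540	1020	540
Ile	1023	408	1009	403	1047	417	1045	417	1020	600
Ile	2180	570	2170	580	2178	578	2220	540	2220	540
Ile	2160	1032	2165	1042	2195	1052	2210	1003	2220	1020
Tyr	1920	1778	1920	1787	1920	1782	1920	1790	1920	1830
Tyr	2396	1788	2253	1784	2355	1786	2358	1780	2340	1830
Tyr	2304	1877	2253	1848	2356	1836	2356	1848	2362	1920
Tyr	4073	4067	4090	3946	4094	3961	4095	3952	4316	4139
Phe	2340	1853	2354	1906	2261	1778	2360	1848	2390	1868
Phe	2340	1934	2254	1960	2254	1926	2260	1913	2390	1970
Phe	4362	4193	4362	4193	4368	4193	4370	4197	4453	4422
Phe	4362	4273	4362	4275	4368	4273	4370	4286	4453	4394
Glu	1373	1102	1354	1106	1354	1106	1349	1106	1470	1260
Glu	2337	1043	2337	1057	2344	1048	2333	1062	2258	1278
Glu	2341	1278	2344	1269	2341	1288	2333	1278	2258	1468
Gln	1295	1100	1281	1100	1284	1071	1288	1100	1260	1200
Gln	1378	1220	1384	1200	1389	1210	1370	1230	1380	1200
Gln	2190	1269	2186	1288	2191	1288	2194	1288	2220	1200
Gln	2225	1370	2227	1367	2210	1380	2208	1369	2220	1380
Lys	1740	809	NP	NP	1736	783	NP	NP	1800	840
Lys	1844	893	NP	NP	1836	898	NP	NP	1800	900
Lys	1836	1062	NP	NP	1836	1058	NP	NP	1806	1032
Lys	2295	962	NP	NP	2290	962	NP	NP	2220	900
Lys	2282	1057	NP	NP	2278	1044	NP	NP	2250	1032
Lys	2282	1118	NP	NP	2286	1119	NP	NP	2250	1137
FAT 1	NP	NP	616	405	600	420	NP	NP	600	420
FAT 2	NP	NP	789	545	789	531	789	545	785	535
FAT 3	NP	NP	1230	614	1245	620	NP	NP	1260	600
FAT 3	NP	NP	1240	1080	1260	1080	NP	NP	1260	1050
FAT 4	NP	NP	1715	772	1705	778	NP	NP	1792	766
FAT 5	NP	NP	3139	607	3150	607	NP	NP	3180	540
FAT 5	NP	NP	3138	1052	3150	1052	NP	NP	3180	1080
FAT 5	NP	NP	3140	1217	3150	1219	NP	NP	3180	1260
Lac	2499	715	2494	709	2494	715	2494	720	2463	790
Thr	2160	789	2160	790	2160	720	2160	720	2160	780
Thr	2578	789	2537	790	2582	720	2573	720	2580	780
Pro	1879	1238	1869	1230	1873	1238	NP	NP	1980	1200
Pro	2408	1246	2408	1234	2408	1238	NP	NP	2472	1213
Pro	2408	1438	2435	1448	2405	1439	NP	NP	2472	1402
Ala	2270	723	2295	696	2295	705	2291	701	2256	876
Val	1350	632	1383	619	1394	619	1383	619	1380	617
Val	1875	1237	1890	1259	1880	1244	1870	1240	2160	617
Met	1518	1187	1523	1197	1518	1177	NP	NP	1560	1260
Met	2338	1270	2342	1274	2351	1277	NP	NP	2340	1260
Met	2338	1370	2342	1367	2351	1380	NP	NP	2340	1320
pEtN	2317	1852	2305	1848	2331	1865	2307	1849	2430	1950
GroPEtn	2300	1791	2291	1781	2293	1791	2292	1791	2300	1791
ChoP	2454	1950	2455	1953	2458	1954	2454	1947	2572	2187
GPC	2127	1943	2121	1943	2124	1939	2123	1939	2160	1980
GPC	2552	2333	2535	2338	2544	2359	2533	2348	2580	2340
Arg	1144	1000	1140	975	1143	984	1146	980	1120	920
Arg	1910	960	1920	960	1944	988	1928	988	1920	960
Arg	1974	1134	1978	1134	1986	1115	1969	1130	1920	1140
MI	NP	NP	2039	1880	2044	1869	2036	1869	2040	1800
MI	NP	NP	2088	1882	2093	1872	2087	1866	2112	1959
MI	NP	NP	2154	1970	2159	1977	2152	1972	2167	1959
MI	NP	NP	2460	2156	2452	2140	2452	2149	2423	2113
Asp	2390	1574	NP	NP	2398	1578	NP	NP	2400	1800
Asp	1870	1750	NP	NP	1876	1768	NP	NP	1800	1740
Tau	NP	NP	2064	1809	2065	1812	2063	1812	2040	1980
α-Glc	3135	2119	3125	2139	3137	2132	3140	2112	3130	2112
α-Glc	3135	2238	3125	2254	3137	2263	3140	2280	3130	2224
α-Glc	3135	2573	3125	2558	3132	2562	3140	2565	3130	2568
β-Glc	2760	1937	2774	1928	2765	1931	2759	1936	2778	1938
β-Glc	2717	2055	2714	2065	2717	2063	2717	2068	2778	2084
β-Glc	2717	2008	2714	2000	2712	2002	2714	2089	2778	2081
ATP	3620	2587	3640	2581	NP	NP	NP	NP	3620	2587
ATP	3620	2680	3640	2628	NP	NP	NP	NP	3620	2680
ADP	3569	2496	3566	2503	3566	2501	3570	2498	3569	2496
ADP	3569	2700	3566	2706	3569	2708	3569	2690	3569	2700
ADP	3569	2762	3566	2759	3569	2769	3569	2765	3569	2760
ADP	3569	2882	3566	2885	3569	2870	3569	2868	3569	2880
NAD+	5310	5110	NP	NP	5302	5106	NP	NP	5200	5110
1-MNA	NP	NP	5218	4718	5218	4725	NP	NP	5341	4921
1-MNA	NP	NP	5412	4718	5412	4725	NP	NP	5581	4921
1-MNA	NP	NP	5520	5328	5512	5321	NP	NP	5581	5341
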