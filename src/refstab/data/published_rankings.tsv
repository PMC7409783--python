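# Published per-method stability statistics for eight candidate reference
# genes across four Schistocerca species (head and thorax panels, five
# isolated- plus five crowded-reared individuals each).  Columns give each
# method's reported rank and value plus the published comprehensive rank
# (geometric mean of the three per-method ranks, re-ranked ascending).
species	tissue	gene	genorm_rank	genorm_m	normfinder_rank	normfinder_value	bestkeeper_rank	bestkeeper_sd	bestkeeper_r	comprehensive_rank
piceifrons	head	Act5C	1	0.506	1	0.117	1	0.630	0.993	1
piceifrons	head	Ann	3	0.579	3	0.265	5	0.576	0.894	3
piceifrons	head	Arm	6	0.669	7	0.341	7	0.581	0.742	8
piceifrons	head	EF2	4	0.648	6	0.333	6	0.597	0.761	6
piceifrons	head	GAPDH	7	0.706	5	0.303	8	0.463	0.725	7
piceifrons	head	Hsp70	5	0.668	4	0.295	4	0.710	0.895	4
piceifrons	head	RIBL5	2	0.562	2	0.207	3	0.427	0.911	2
piceifrons	head	Tub	8	0.719	8	0.375	2	0.855	0.931	5
piceifrons	thorax	Act5C	2	0.560	2	0.148	4	0.533	0.925	2
piceifrons	thorax	Ann	1	0.500	1	0.131	1	0.615	0.972	1
piceifrons	thorax	Arm	3	0.592	4	0.241	2	0.747	0.941	3
piceifrons	thorax	EF2	4	0.671	5	0.251	7	0.444	0.676	5
piceifrons	thorax	GAPDH	6	0.749	6	0.262	6	0.527	0.694	7
piceifrons	thorax	Hsp70	5	0.720	3	0.219	5	0.696	0.851	4
piceifrons	thorax	RIBL5	8	0.782	8	0.405	8	0.337	0.477	8
piceifrons	thorax	Tub	7	0.757	7	0.344	3	0.865	0.937	6
americana	head	Act5C	1	0.402	1	0.053	1	0.383	0.944	1
americana	head	Ann	5	0.525	6	0.223	3	0.499	0.868	5
americana	head	Arm	4	0.497	4	0.166	2	0.525	0.906	3
americana	head	EF2	2	0.450	2	0.136	4	0.438	0.856	2
americana	head	GAPDH	8	0.788	8	0.280	7	0.569	0.556	8
americana	head	Hsp70	6	0.579	7	0.263	8	0.328	0.553	7
americana	head	RIBL5	3	0.456	3	0.158	5	0.289	0.826	4
americana	head	Tub	7	0.613	5	0.223	6	0.411	0.715	6
americana	thorax	Act5C	2	0.578	3	0.174	4	0.358	0.820	4
americana	thorax	Ann	7	0.799	7	0.250	5	0.679	0.784	7
americana	thorax	Arm	4	0.627	2	0.111	2	0.559	0.850	3
americana	thorax	EF2	3	0.601	4	0.176	1	0.485	0.853	2
americana	thorax	GAPDH	8	1.435	8	0.432	8	0.855	0.416	8
americana	thorax	Hsp70	5	0.634	6	0.189	7	0.287	0.522	6
americana	thorax	RIBL5	1	0.548	1	0.098	3	0.284	0.837	1
americana	thorax	Tub	6	0.712	5	0.182	6	0.566	0.700	5
cubense	head	Act5C	1	0.385	2	0.097	2	0.332	0.896	1
cubense	head	Ann	6	0.540	7	0.225	7	0.457	0.707	7
cubense	head	Arm	5	0.421	3	0.111	1	0.415	0.905	3
cubense	head	EF2	3	0.410	5	0.145	5	0.279	0.815	4
cubense	head	GAPDH	8	0.590	8	0.238	8	0.418	0.539	8
cubense	head	Hsp70	2	0.400	1	0.095	3	0.305	0.872	2
cubense	head	RIBL5	4	0.413	4	0.118	6	0.263	0.733	5
cubense	head	Tub	7	0.548	6	0.169	4	0.542	0.841	6
cubense	thorax	Act5C	6	0.390	5	0.101	3	0.390	0.840	5
cubense	thorax	Ann	4	0.383	2	0.091	2	0.414	0.861	2
cubense	thorax	Arm	2	0.368	4	0.098	4	0.360	0.814	3
cubense	thorax	EF2	7	0.397	7	0.111	5	0.384	0.788	7
cubense	thorax	GAPDH	3	0.378	3	0.097	7	0.263	0.721	4
cubense	thorax	Hsp70	1	0.350	1	0.075	1	0.337	0.893	1
cubense	thorax	RIBL5	5	0.387	6	0.110	8	0.273	0.708	6
cubense	thorax	Tub	8	0.458	8	0.129	6	0.406	0.752	8
nitens	head	Act5C	2	0.529	2	0.158	4	0.453	0.916	2
nitens	head	Ann	1	0.528	1	0.139	5	0.282	0.867	1
nitens	head	Arm	6	0.714	7	0.248	1	0.601	0.935	4
nitens	head	EF2	5	0.621	6	0.214	2	0.646	0.933	5
nitens	head	GAPDH	7	0.721	5	0.199	7	0.482	0.584	7
nitens	head	Hsp70	4	0.578	3	0.178	3	0.539	0.924	3
nitens	head	RIBL5	3	0.567	4	0.198	6	0.439	0.792	6
nitens	head	Tub	8	0.749	8	0.277	8	0.266	0.074	8
nitens	thorax	Act5C	4	0.517	3	0.101	5	0.281	0.778	4
nitens	thorax	Ann	1	0.448	1	0.020	1	0.270	0.934	1
nitens	thorax	Arm	3	0.499	2	0.057	2	0.433	0.868	2
nitens	thorax	EF2	6	0.656	5	0.157	6	0.526	0.727	6
nitens	thorax	GAPDH	7	0.710	4	0.135	7	0.595	0.703	7
nitens	thorax	Hsp70	5	0.549	6	0.164	3	0.449	0.866	5
nitens	thorax	RIBL5	2	0.471	7	0.170	4	0.300	0.819	3
nitens	thorax	Tub	8	0.736	8	1.628	8	0.610	0.691	8
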