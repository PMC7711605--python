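group	variable	communality	f1	f2	f3	f4	f5	f6	f7	f8	f9
1	LACS1.1	0.951	1.028	0.174	-0.081	0.062	0.085	-0.034	0.001	-0.056	0.003
1	POT2	0.953	0.984	0.125	-0.060	0.333	0.012	-0.129	0.010	0.102	0.042
1	POX1	0.900	0.966	0.243	0.003	0.135	0.075	-0.266	0.171	0.109	0.028
1	FOX2	0.960	0.965	-0.021	-0.061	0.097	0.037	0.044	0.119	-0.074	-0.036
1	FBP1	0.907	0.957	0.261	-0.057	-0.067	0.354	-0.055	-0.084	-0.079	-0.249
1	CIT3	0.899	0.942	0.107	-0.088	0.015	0.180	0.044	-0.054	0.181	0.082
1	CIT2	0.913	0.912	0.042	0.083	-0.043	-0.086	0.065	0.044	0.131	0.016
1	ALDH	0.910	0.883	-0.097	0.011	-0.143	0.108	0.153	-0.089	-0.080	0.074
1	TGL4	0.914	0.871	0.082	0.046	0.109	-0.096	0.282	-0.131	-0.006	0.002
1	TGL3	0.825	0.851	0.035	0.120	0.118	0.052	-0.192	-0.236	-0.204	0.335
1	ARE2	0.932	0.793	-0.395	0.099	-0.072	0.027	0.008	-0.005	0.016	-0.135
1	ARE1	0.822	0.781	-0.223	0.375	-0.045	0.066	-0.233	0.193	0.312	-0.002
1	POT1	0.899	0.720	-0.038	-0.021	-0.085	-0.050	0.174	-0.169	0.037	0.397
1	ERG13	0.905	-0.688	0.129	0.441	0.029	0.002	-0.048	-0.063	-0.030	0.060
1	PCK1	0.782	0.686	-0.282	-0.082	-0.130	0.510	0.037	-0.043	0.182	0.074
1	ERG10	0.915	-0.649	0.127	0.372	0.132	0.042	0.044	0.150	-0.012	-0.013
1	ACO2	0.847	-0.641	0.024	-0.110	0.030	0.109	0.046	0.565	0.133	-0.077
1	LAT1	0.929	-0.605	-0.001	0.342	-0.043	0.324	0.089	0.252	-0.102	0.135
1	PDX1	0.962	-0.595	0.283	0.461	-0.181	0.067	-0.013	0.161	-0.015	0.048
1	PYC2	0.787	0.584	-0.047	0.255	-0.199	0.033	0.279	-0.306	0.323	0.094
1	DGK1	0.846	-0.555	0.299	-0.035	0.257	-0.002	-0.372	-0.115	0.100	-0.281
1	AYR1	0.843	0.551	-0.313	0.175	0.261	-0.301	0.207	0.200	-0.330	-0.044
1	PDA1	0.897	-0.422	0.264	0.378	-0.111	0.276	-0.016	0.210	-0.096	-0.020
1	SDH2	0.874	0.340	0.303	-0.082	0.335	0.310	0.119	0.315	-0.196	0.153
2	PFK2	0.837	-0.118	0.949	0.001	0.028	-0.140	0.017	-0.040	0.171	0.027
2	HXK2	0.882	0.007	0.919	0.074	0.118	-0.196	-0.311	-0.143	-0.098	0.091
2	MDH2	0.908	-0.129	0.903	-0.045	-0.060	-0.037	0.078	0.141	0.028	-0.001
2	ACS1	0.841	0.396	0.894	0.259	-0.063	-0.109	0.104	-0.163	0.364	0.023
2	ZWF1	0.907	0.050	0.868	0.044	0.104	-0.197	0.097	-0.062	-0.270	-0.105
2	PGM1	0.891	0.474	0.854	0.075	0.230	-0.330	-0.092	-0.031	-0.212	0.218
2	LRO1	0.600	-0.235	0.806	-0.186	-0.324	-0.195	0.237	-0.251	0.135	0.112
2	FUM1	0.882	-0.109	0.794	-0.244	-0.104	0.071	-0.196	0.362	0.044	0.135
2	PGI1	0.891	0.327	0.792	0.092	0.195	0.217	0.025	-0.276	-0.109	-0.132
2	KGD2	0.947	-0.299	0.779	-0.199	-0.203	0.321	0.025	-0.207	0.018	-0.031
2	LSC2	0.976	-0.386	0.761	-0.091	0.048	0.126	-0.077	-0.087	-0.052	0.009
2	CIT1	0.885	0.326	0.743	0.292	-0.178	0.277	0.003	0.041	-0.022	0.083
2	IDH2	0.900	-0.186	0.740	-0.285	-0.071	0.355	-0.066	0.042	0.052	-0.011
2	SDH1	0.957	0.415	0.716	-0.383	0.156	0.041	0.003	0.334	0.060	-0.225
2	GND1	0.911	-0.024	0.714	0.256	-0.047	0.062	0.042	-0.073	-0.258	-0.073
2	ENO1	0.919	-0.102	0.683	0.205	0.076	0.107	-0.058	0.094	-0.066	0.242
2	PGK1	0.922	-0.293	0.620	0.264	-0.063	0.050	0.147	0.065	-0.151	0.016
2	GUT2	0.836	0.479	0.597	-0.040	-0.401	-0.145	-0.233	0.582	-0.086	0.004
2	CDC19	0.932	-0.147	0.585	0.393	0.163	-0.020	-0.020	0.055	0.056	-0.171
2	HMG1	0.644	-0.211	0.464	0.081	0.365	-0.088	0.259	-0.123	0.323	-0.074
2	LSC1	0.927	-0.415	0.417	0.008	0.199	0.298	-0.280	-0.124	-0.102	-0.010
3	PAH1	0.840	0.234	0.039	0.931	-0.245	-0.069	-0.010	0.006	0.034	0.084
3	SCT1	0.925	0.090	-0.400	0.924	0.031	0.086	0.077	-0.004	-0.045	0.243
3	ACC1	0.861	-0.049	-0.105	0.923	0.130	-0.125	0.060	0.006	0.067	0.045
3	SLC1	0.921	0.121	-0.092	0.899	-0.238	-0.127	-0.361	0.007	-0.103	-0.139
3	DGA2	0.851	0.104	-0.113	0.882	-0.158	-0.085	-0.209	-0.023	-0.077	0.239
3	FAS1.1	0.865	-0.328	0.016	0.833	0.017	-0.116	-0.013	-0.081	0.012	0.038
3	ACL1	0.974	-0.182	0.313	0.793	0.089	-0.228	-0.013	-0.014	0.042	-0.021
3	GPD1	0.878	0.240	0.287	0.728	-0.300	0.316	-0.328	0.087	0.164	-0.037
3	FAS2.1	0.865	-0.165	0.409	0.721	-0.073	-0.298	0.017	-0.024	0.050	0.047
3	ACL2	0.971	-0.254	0.421	0.692	0.065	-0.222	0.028	-0.027	0.045	-0.005
3	MDH1	0.882	0.458	0.270	0.673	-0.090	0.309	0.123	0.042	0.017	0.065
3	FAA1	0.728	0.130	0.363	0.578	0.031	-0.349	0.149	0.226	0.050	-0.064
3	FBP2	0.913	0.008	0.204	0.568	0.196	0.325	0.321	-0.134	0.055	-0.009
3	oil productivity	0.382	-0.252	-0.105	0.556	-0.059	0.032	-0.062	-0.008	0.053	0.111
3	tid_2139	0.645	-0.433	-0.173	0.532	0.430	0.167	-0.055	0.181	0.097	-0.078
3	PDB1	0.891	-0.300	0.296	0.421	-0.013	0.324	0.086	0.103	-0.038	-0.039
4	YEH2	0.729	-0.095	0.117	0.153	-0.962	0.060	-0.147	0.223	0.054	0.117
4	K_6707	0.956	0.200	0.023	0.243	-0.931	-0.083	0.059	0.329	0.001	-0.025
4	PYC1	0.786	0.040	0.124	-0.071	0.820	0.004	0.169	-0.023	-0.014	-0.057
4	LACS1.2	0.734	-0.308	-0.087	-0.193	-0.799	0.192	0.459	0.157	-0.474	-0.016
4	FAS2.2	0.821	0.138	0.115	-0.186	-0.722	-0.304	0.151	0.100	0.188	0.025
4	ACO1	0.889	0.317	0.219	-0.255	0.624	0.165	-0.059	0.308	-0.030	-0.029
4	MAE1	0.702	0.155	-0.558	0.098	0.564	0.115	0.072	0.006	0.057	0.262
4	SDH3	0.746	0.000	0.370	-0.109	0.538	-0.044	0.202	0.144	-0.129	-0.105
4	tid_69043	0.708	-0.059	0.194	0.255	0.382	0.169	0.313	-0.046	-0.264	0.179
5	KGD1	0.656	0.206	-0.199	-0.016	0.070	0.824	0.170	-0.040	0.085	0.025
5	IDH1	0.900	-0.140	0.277	-0.367	0.129	0.664	0.179	0.078	0.053	0.099
5	TPI1	0.775	-0.052	0.061	0.201	0.214	0.619	0.338	-0.213	0.078	-0.022
5	IDP1	0.693	0.199	0.403	-0.346	0.184	0.605	0.092	-0.106	0.045	0.054
5	LPD1	0.819	-0.306	0.482	-0.096	-0.249	0.515	0.219	-0.248	0.115	-0.013
6	CDS1	0.760	-0.034	-0.049	0.125	-0.034	-0.243	-0.815	0.256	-0.028	-0.013
6	ALE1	0.796	-0.056	0.244	0.219	-0.196	-0.384	-0.648	0.105	-0.132	-0.072
6	K_291711	0.815	0.425	0.288	-0.016	-0.120	-0.036	0.574	0.003	-0.283	-0.160
6	GAP1	0.712	-0.184	-0.212	0.297	0.243	0.133	0.544	0.067	-0.041	0.197
6	EMI2	0.766	0.223	0.272	0.293	0.283	0.066	0.478	-0.089	-0.084	0.143
6	SHH4	0.882	0.431	-0.099	-0.111	0.417	0.347	0.439	0.071	0.147	-0.339
7	TGL1	0.611	0.157	0.135	-0.052	0.209	0.151	0.201	-0.828	0.219	0.192
8	TPI2.2	0.730	0.377	-0.038	0.033	-0.237	0.273	0.093	-0.269	0.616	-0.082
8	TPI2.1	0.792	0.414	-0.428	0.231	-0.008	0.122	-0.064	-0.079	0.603	0.004
8	FAS1.2	0.560	-0.460	0.009	-0.305	-0.059	0.066	0.059	-0.114	0.478	-0.008
9	PDC1	0.851	0.167	0.030	0.426	-0.068	0.179	0.246	-0.272	0.022	0.665
9	DGA1	0.684	0.357	0.044	0.427	-0.183	-0.063	-0.103	0.099	-0.235	0.554
9	PDC2	0.846	0.043	-0.404	0.160	-0.179	0.022	0.021	-0.318	0.209	0.518
9	SOL3	0.768	-0.153	0.166	0.298	0.461	0.089	-0.134	-0.300	0.028	0.497
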