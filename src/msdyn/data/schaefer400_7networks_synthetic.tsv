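roi_id	network
ROI001	VN
ROI002	VN
ROI003	VN
ROI004	VN
ROI005	VN
ROI006	VN
ROI007	VN
ROI008	VN
ROI009	VN
ROI010	VN
ROI011	VN
ROI012	VN
ROI013	VN
ROI014	VN
ROI015	VN
ROI016	VN
ROI017	VN
ROI018	VN
ROI019	VN
ROI020	VN
ROI021	VN
ROI022	VN
ROI023	VN
ROI024	VN
ROI025	VN
ROI026	VN
ROI027	VN
ROI028	VN
ROI029	VN
ROI030	VN
ROI031	VN
ROI032	VN
ROI033	VN
ROI034	VN
ROI035	VN
ROI036	VN
ROI037	VN
ROI038	VN
ROI039	VN
ROI040	VN
ROI041	VN
ROI042	VN
ROI043	VN
ROI044	VN
ROI045	VN
ROI046	VN
ROI047	VN
ROI048	VN
ROI049	VN
ROI050	VN
ROI051	VN
ROI052	VN
ROI053	VN
ROI054	VN
ROI055	VN
ROI056	VN
ROI057	VN
ROI058	VN
ROI059	VN
ROI060	VN
ROI061	VN
ROI062	SMN
ROI063	SMN
ROI064	SMN
ROI065	SMN
ROI066	SMN
ROI067	SMN
ROI068	SMN
ROI069	SMN
ROI070	SMN
ROI071	SMN
ROI072	SMN
ROI073	SMN
ROI074	SMN
ROI075	SMN
ROI076	SMN
ROI077	SMN
ROI078	SMN
ROI079	SMN
ROI080	SMN
ROI081	SMN
ROI082	SMN
ROI083	SMN
ROI084	SMN
ROI085	SMN
ROI086	SMN
ROI087	SMN
ROI088	SMN
ROI089	SMN
ROI090	SMN
ROI091	SMN
ROI092	SMN
ROI093	SMN
ROI094	SMN
ROI095	SMN
ROI096	SMN
ROI097	SMN
ROI098	SMN
ROI099	SMN
ROI100	SMN
ROI101	SMN
ROI102	SMN
ROI103	SMN
ROI104	SMN
ROI105	SMN
ROI106	SMN
ROI107	SMN
ROI108	SMN
ROI109	SMN
ROI110	SMN
ROI111	SMN
ROI112	SMN
ROI113	SMN
ROI114	SMN
ROI115	SMN
ROI116	SMN
ROI117	SMN
ROI118	SMN
ROI119	SMN
ROI120	SMN
ROI121	SMN
ROI122	SMN
ROI123	SMN
ROI124	SMN
ROI125	SMN
ROI126	SMN
ROI127	SMN
ROI128	SMN
ROI129	SMN
ROI130	SMN
ROI131	SMN
ROI132	SMN
ROI133	SMN
ROI134	SMN
ROI135	SMN
ROI136	SMN
ROI137	SMN
ROI138	SMN
ROI139	DAN
ROI140	DAN
ROI141	DAN
ROI142	DAN
ROI143	DAN
ROI144	DAN
ROI145	DAN
ROI146	DAN
ROI147	DAN
ROI148	DAN
ROI149	DAN
ROI150	DAN
ROI151	DAN
ROI152	DAN
ROI153	DAN
ROI154	DAN
ROI155	DAN
ROI156	DAN
ROI157	DAN
ROI158	DAN
ROI159	DAN
ROI160	DAN
ROI161	DAN
ROI162	DAN
ROI163	DAN
ROI164	DAN
ROI165	DAN
ROI166	DAN
ROI167	DAN
ROI168	DAN
ROI169	DAN
ROI170	DAN
ROI171	DAN
ROI172	DAN
ROI173	DAN
ROI174	DAN
ROI175	DAN
ROI176	DAN
ROI177	DAN
ROI178	DAN
ROI179	DAN
ROI180	DAN
ROI181	DAN
ROI182	DAN
ROI183	DAN
ROI184	DAN
ROI185	VAN
ROI186	VAN
ROI187	VAN
ROI188	VAN
ROI189	VAN
ROI190	VAN
ROI191	VAN
ROI192	VAN
ROI193	VAN
ROI194	VAN
ROI195	VAN
ROI196	VAN
ROI197	VAN
ROI198	VAN
ROI199	VAN
ROI200	VAN
ROI201	VAN
ROI202	VAN
ROI203	VAN
ROI204	VAN
ROI205	VAN
ROI206	VAN
ROI207	VAN
ROI208	VAN
ROI209	VAN
ROI210	VAN
ROI211	VAN
ROI212	VAN
ROI213	VAN
ROI214	VAN
ROI215	VAN
ROI216	VAN
ROI217	VAN
ROI218	VAN
ROI219	VAN
ROI220	VAN
ROI221	VAN
ROI222	VAN
ROI223	VAN
ROI224	VAN
ROI225	VAN
ROI226	VAN
ROI227	VAN
ROI228	VAN
ROI229	VAN
ROI230	VAN
ROI231	VAN
ROI232	limbic
ROI233	limbic
ROI234	limbic
ROI235	limbic
ROI236	limbic
ROI237	limbic
ROI238	limbic
ROI239	limbic
ROI240	limbic
ROI241	limbic
ROI242	limbic
ROI243	limbic
ROI244	limbic
ROI245	limbic
ROI246	limbic
ROI247	limbic
ROI248	limbic
ROI249	limbic
ROI250	limbic
ROI251	limbic
ROI252	limbic
ROI253	limbic
ROI254	limbic
ROI255	limbic
ROI256	limbic
ROI257	limbic
ROI258	ECN
ROI259	ECN
ROI260	ECN
ROI261	ECN
ROI262	ECN
ROI263	ECN
ROI264	ECN
ROI265	ECN
ROI266	ECN
ROI267	ECN
ROI268	ECN
ROI269	ECN
ROI270	ECN
ROI271	ECN
ROI272	ECN
ROI273	ECN
ROI274	ECN
ROI275	ECN
ROI276	ECN
ROI277	ECN
ROI278	ECN
ROI279	ECN
ROI280	ECN
ROI281	ECN
ROI282	ECN
ROI283	ECN
ROI284	ECN
ROI285	ECN
ROI286	ECN
ROI287	ECN
ROI288	ECN
ROI289	ECN
ROI290	ECN
ROI291	ECN
ROI292	ECN
ROI293	ECN
ROI294	ECN
ROI295	ECN
ROI296	ECN
ROI297	ECN
ROI298	ECN
ROI299	ECN
ROI300	ECN
ROI301	ECN
ROI302	ECN
ROI303	ECN
ROI304	ECN
ROI305	ECN
ROI306	ECN
ROI307	ECN
ROI308	ECN
ROI309	ECN
ROI310	DMN
ROI311	DMN
ROI312	DMN
ROI313	DMN
ROI314	DMN
ROI315	DMN
ROI316	DMN
ROI317	DMN
ROI318	DMN
ROI319	DMN
ROI320	DMN
ROI321	DMN
ROI322	DMN
ROI323	DMN
ROI324	DMN
ROI325	DMN
ROI326	DMN
ROI327	DMN
ROI328	DMN
ROI329	DMN
ROI330	DMN
ROI331	DMN
ROI332	DMN
ROI333	DMN
ROI334	DMN
ROI335	DMN
ROI336	DMN
ROI337	DMN
ROI338	DMN
ROI339	DMN
ROI340	DMN
ROI341	DMN
ROI342	DMN
ROI343	DMN
ROI344	DMN
ROI345	DMN
ROI346	DMN
ROI347	DMN
ROI348	DMN
ROI349	DMN
ROI350	DMN
ROI351	DMN
ROI352	DMN
ROI353	DMN
ROI354	DMN
ROI355	DMN
ROI356	DMN
ROI357	DMN
ROI358	DMN
ROI359	DMN
ROI360	DMN
ROI361	DMN
ROI362	DMN
ROI363	DMN
ROI364	DMN
ROI365	DMN
ROI366	DMN
ROI367	DMN
ROI368	DMN
ROI369	DMN
ROI370	DMN
ROI371	DMN
ROI372	DMN
ROI373	DMN
ROI374	DMN
ROI375	DMN
ROI376	DMN
ROI377	DMN
ROI378	DMN
ROI379	DMN
ROI380	DMN
ROI381	DMN
ROI382	DMN
ROI383	DMN
ROI384	DMN
ROI385	DMN
ROI386	DMN
ROI387	DMN
ROI388	DMN
ROI389	DMN
ROI390	DMN
ROI391	DMN
ROI392	DMN
ROI393	DMN
ROI394	DMN
ROI395	DMN
ROI396	DMN
ROI397	DMN
ROI398	DMN
ROI399	DMN
ROI400	DMN
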