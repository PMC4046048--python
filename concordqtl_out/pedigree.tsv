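animal_id	sire_id	dam_id
A0000	0	0
A0001	0	0
A0002	0	0
A0003	0	0
A0004	0	0
A0005	0	0
A0006	0	0
A0007	0	0
A0008	0	0
A0009	0	0
A0010	0	0
A0011	0	0
A0012	0	0
A0013	0	0
A0014	0	0
A0015	0	0
A0016	0	0
A0017	0	0
A0018	0	0
A0019	0	0
A0020	0	0
A0021	0	0
A0022	0	0
A0023	0	0
A0024	0	0
A0025	0	0
A0026	0	0
A0027	0	0
A0028	0	0
A0029	0	0
A0030	0	0
A0031	0	0
A0032	0	0
A0033	0	0
A0034	0	0
A0035	0	0
A0036	0	0
A0037	0	0
A0038	0	0
A0039	0	0
A0040	0	0
A0041	0	0
A0042	0	0
A0043	0	0
A0044	0	0
A0045	0	0
A0046	0	0
A0047	0	0
A0048	0	0
A0049	0	0
A0050	0	0
A0051	0	0
A0052	0	0
A0053	0	0
A0054	0	0
A0055	0	0
A0056	0	0
A0057	0	0
A0058	0	0
A0059	0	0
A0060	0	0
A0061	0	0
A0062	0	0
A0063	0	0
A0064	0	0
A0065	0	0
A0066	0	0
A0067	0	0
A0068	0	0
A0069	0	0
A0070	0	0
A0071	0	0
A0072	0	0
A0073	0	0
A0074	0	0
A0075	0	0
A0076	0	0
A0077	0	0
A0078	0	0
A0079	0	0
A0080	0	0
A0081	0	0
A0082	0	0
A0083	0	0
A0084	0	0
A0085	0	0
A0086	0	0
A0087	0	0
A0088	0	0
A0089	0	0
A0090	0	0
A0091	0	0
A0092	0	0
A0093	0	0
A0094	0	0
A0095	0	0
A0096	0	0
A0097	0	0
A0098	0	0
A0099	0	0
A0100	0	0
A0101	0	0
A0102	0	0
A0103	0	0
A0104	0	0
A0105	0	0
A0106	0	0
A0107	0	0
A0108	0	0
A0109	0	0
A0110	0	0
A0111	0	0
A0112	0	0
A0113	0	0
A0114	0	0
A0115	0	0
A0116	0	0
A0117	0	0
A0118	0	0
A0119	0	0
A0120	0	0
A0121	0	0
A0122	0	0
A0123	0	0
A0124	0	0
A0125	0	0
A0126	0	0
A0127	0	0
A0128	0	0
A0129	0	0
A0130	0	0
A0131	0	0
A0132	0	0
A0133	0	0
A0134	0	0
A0135	0	0
A0136	0	0
A0137	0	0
A0138	0	0
A0139	0	0
A0140	0	0
A0141	0	0
A0142	0	0
A0143	0	0
A0144	0	0
A0145	0	0
A0146	0	0
A0147	0	0
A0148	0	0
A0149	0	0
A0150	0	0
A0151	0	0
A0152	0	0
A0153	0	0
A0154	0	0
A0155	0	0
A0156	0	0
A0157	0	0
A0158	0	0
A0159	0	0
A0160	0	0
A0161	0	0
A0162	0	0
A0163	0	0
A0164	0	0
A0165	0	0
A0166	0	0
A0167	0	0
A0168	0	0
A0169	0	0
A0170	0	0
A0171	0	0
A0172	0	0
A0173	0	0
A0174	0	0
A0175	0	0
A0176	0	0
A0177	0	0
A0178	0	0
A0179	0	0
A0180	0	0
A0181	0	0
A0182	0	0
A0183	0	0
A0184	0	0
A0185	0	0
A0186	0	0
A0187	0	0
A0188	0	0
A0189	0	0
A0190	0	0
A0191	0	0
A0192	0	0
A0193	0	0
A0194	0	0
A0195	0	0
A0196	0	0
A0197	0	0
A0198	0	0
A0199	0	0
A0200	0	0
A0201	0	0
A0202	0	0
A0203	0	0
A0204	0	0
A0205	0	0
A0206	0	0
A0207	0	0
A0208	0	0
A0209	0	0
A0210	0	0
A0211	0	0
A0212	0	0
A0213	0	0
A0214	0	0
A0215	0	0
A0216	0	0
A0217	0	0
A0218	0	0
A0219	0	0
A0220	0	0
A0221	0	0
A0222	0	0
A0223	0	0
A0224	0	0
A0225	0	0
A0226	0	0
A0227	0	0
A0228	0	0
A0229	0	0
A0230	0	0
A0231	0	0
A0232	0	0
A0233	0	0
A0234	0	0
A0235	0	0
A0236	0	0
A0237	0	0
A0238	0	0
A0239	0	0
A0240	0	0
A0241	0	0
A0242	0	0
A0243	0	0
A0244	0	0
A0245	0	0
A0246	0	0
A0247	0	0
A0248	0	0
A0249	0	0
A0250	0	0
A0251	0	0
A0252	0	0
A0253	0	0
A0254	0	0
A0255	0	0
A0256	0	0
A0257	0	0
A0258	0	0
A0259	0	0
A0260	0	0
A0261	0	0
A0262	0	0
A0263	0	0
A0264	0	0
A0265	0	0
A0266	0	0
A0267	0	0
A0268	0	0
A0269	0	0
A0270	0	0
A0271	0	0
A0272	0	0
A0273	0	0
A0274	0	0
A0275	0	0
A0276	0	0
A0277	0	0
A0278	0	0
A0279	0	0
A0280	0	0
A0281	0	0
A0282	0	0
A0283	0	0
A0284	0	0
A0285	0	0
A0286	0	0
A0287	0	0
A0288	0	0
A0289	0	0
A0290	0	0
A0291	0	0
A0292	0	0
A0293	0	0
A0294	0	0
A0295	0	0
A0296	0	0
A0297	0	0
A0298	0	0
A0299	0	0
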