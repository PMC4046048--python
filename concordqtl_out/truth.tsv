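animal_id	qtl_genotype	status	true_bv
A0000	0	hom	-0.4645338927
A0001	0	hom	-0.37399726
A0002	0	hom	-0.1530375082
A0003	1	het	0.08212526178
A0004	1	het	0.5767011451
A0005	2	hom	1.462045539
A0006	1	het	0.416713004
A0007	2	hom	1.785873414
A0008	1	het	-0.3464761069
A0009	1	het	-0.06416708046
A0010	0	hom	-0.8198648297
A0011	1	het	0.06300113376
A0012	1	het	0.05835910553
A0013	1	het	-0.7185247595
A0014	2	hom	-0.30637715
A0015	0	hom	-1.114993686
A0016	1	het	-0.02063973019
A0017	1	het	-0.6586602967
A0018	1	het	-0.4080716673
A0019	1	het	0.641414626
A0020	2	hom	0.8415755704
A0021	0	hom	-0.4509978954
A0022	0	hom	-0.8971062345
A0023	0	hom	-1.101222459
A0024	1	het	0.6002267444
A0025	1	het	-0.1527588425
A0026	0	hom	-0.160864516
A0027	0	hom	0.03525370843
A0028	0	hom	-1.317885781
A0029	1	het	0.7419992274
A0030	0	hom	-0.7377813316
A0031	0	hom	-0.5245967439
A0032	0	hom	-1.230985532
A0033	0	hom	-0.5554100407
A0034	2	hom	1.688555547
A0035	1	het	0.1284463929
A0036	1	het	-0.2879179585
A0037	0	hom	-0.4102756613
A0038	0	hom	0.06095954379
A0039	0	hom	0.09273892338
A0040	1	het	-0.189111512
A0041	1	het	-0.5570673161
A0042	0	hom	-0.6685743954
A0043	0	hom	-0.6485346983
A0044	1	het	0.2041912582
A0045	0	hom	-0.04339367404
A0046	0	hom	0.01559250884
A0047	1	het	0.2940430195
A0048	0	hom	-0.7019178216
A0049	1	het	0.6780791999
A0050	1	het	0.2605443653
A0051	0	hom	0.20376967
A0052	0	hom	-0.4955937218
A0053	1	het	0.01460496871
A0054	0	hom	-1.141055194
A0055	1	het	-0.2569512095
A0056	0	hom	-1.476248666
A0057	0	hom	-0.03517654971
A0058	2	hom	0.8163941681
A0059	0	hom	-1.06296841
A0060	0	hom	-0.7134080286
A0061	0	hom	-0.5592963881
A0062	1	het	0.2984547001
A0063	1	het	0.9259306562
A0064	1	het	0.4890865691
A0065	1	het	-0.2374617388
A0066	0	hom	-0.9093433793
A0067	1	het	0.7305450258
A0068	1	het	0.2528635472
A0069	2	hom	1.602020233
A0070	1	het	0.9593080554
A0071	0	hom	-1.002833097
A0072	1	het	-0.2213456525
A0073	1	het	0.4269099087
A0074	0	hom	-0.8626875469
A0075	0	hom	-0.5926988685
A0076	0	hom	-0.9972392422
A0077	1	het	0.2285270538
A0078	1	het	-0.3186035111
A0079	1	het	-0.9287150993
A0080	0	hom	-0.4151259107
A0081	1	het	0.9204390631
A0082	2	hom	0.7177497394
A0083	1	het	0.3247637842
A0084	2	hom	0.5031312314
A0085	0	hom	-0.8440212693
A0086	0	hom	-0.7193104781
A0087	0	hom	-0.2135714695
A0088	0	hom	-0.9162136795
A0089	1	het	-0.3558283065
A0090	0	hom	-0.1896205198
A0091	1	het	0.04969310287
A0092	0	hom	-0.4568452741
A0093	1	het	-0.5633786574
A0094	0	hom	0.6512088194
A0095	0	hom	-0.09260774142
A0096	0	hom	0.3307852832
A0097	0	hom	-0.2058436077
A0098	2	hom	1.2279145
A0099	1	het	0.1319113773
A0100	1	het	0.3047758784
A0101	2	hom	1.25473956
A0102	0	hom	-0.5789286448
A0103	0	hom	0.5336344921
A0104	1	het	0.4171350581
A0105	0	hom	-0.1266265146
A0106	1	het	0.2690434519
A0107	1	het	1.245338752
A0108	0	hom	-0.9465139527
A0109	0	hom	-0.1419056389
A0110	1	het	0.8048176215
A0111	1	het	0.3866585951
A0112	2	hom	-0.0108057112
A0113	0	hom	-0.1495877532
A0114	1	het	0.02658126009
A0115	2	hom	1.402157533
A0116	0	hom	-0.1480970497
A0117	0	hom	-0.9002169936
A0118	1	het	0.3060069511
A0119	0	hom	-0.3897698776
A0120	1	het	-0.1541198138
A0121	0	hom	0.1673786723
A0122	0	hom	-0.3666579092
A0123	0	hom	-0.6571185143
A0124	1	het	-0.4171805563
A0125	0	hom	-1.312307976
A0126	1	het	-0.321849157
A0127	1	het	-0.3359275264
A0128	0	hom	-0.1193444925
A0129	1	het	0.2566134409
A0130	0	hom	-1.153268144
A0131	2	hom	-0.3160992881
A0132	1	het	0.05509047501
A0133	0	hom	0.1596950941
A0134	0	hom	-0.5272474615
A0135	1	het	0.8864228239
A0136	0	hom	-0.3937875222
A0137	1	het	-0.2476706141
A0138	1	het	-0.4010708288
A0139	0	hom	0.009083367351
A0140	1	het	0.6569302458
A0141	2	hom	1.008544863
A0142	0	hom	0.05171675892
A0143	0	hom	-0.2695128597
A0144	0	hom	-0.8414375198
A0145	1	het	-0.1838849283
A0146	0	hom	-0.5683680989
A0147	1	het	0.1578122099
A0148	1	het	0.06979682306
A0149	2	hom	0.7235059723
A0150	1	het	0.1501470735
A0151	0	hom	-1.111283104
A0152	0	hom	0.4342298583
A0153	1	het	-0.3483167068
A0154	1	het	0.8056219199
A0155	1	het	0.1958572675
A0156	0	hom	-0.5481270997
A0157	0	hom	-1.048669986
A0158	1	het	1.081674186
A0159	1	het	0.4489401372
A0160	0	hom	-0.5375491153
A0161	1	het	0.04884607776
A0162	0	hom	-1.155566264
A0163	1	het	0.4005319921
A0164	0	hom	-0.890871657
A0165	0	hom	0.2588898367
A0166	0	hom	0.7897110606
A0167	1	het	0.04400436979
A0168	1	het	-0.8650042114
A0169	1	het	0.2153963671
A0170	1	het	0.9943392616
A0171	0	hom	-0.04998257127
A0172	1	het	0.3617067474
A0173	1	het	-0.0981322277
A0174	0	hom	-0.7518051204
A0175	1	het	0.3223077734
A0176	1	het	-0.09141483712
A0177	1	het	0.3674414465
A0178	2	hom	0.8563805221
A0179	0	hom	-0.4540466773
A0180	0	hom	-0.1287862019
A0181	0	hom	-0.5648475337
A0182	1	het	-0.1328430399
A0183	1	het	0.3215563479
A0184	2	hom	0.6530538991
A0185	0	hom	-0.2536959936
A0186	1	het	0.7839193329
A0187	1	het	0.531447909
A0188	0	hom	0.09047804933
A0189	1	het	0.7826012755
A0190	1	het	-0.0001760063294
A0191	0	hom	0.1027241014
A0192	0	hom	0.2156251454
A0193	1	het	0.162947056
A0194	0	hom	-0.1238678685
A0195	0	hom	-0.3760694281
A0196	0	hom	-0.6716153336
A0197	0	hom	-0.001850302478
A0198	1	het	-0.4225277893
A0199	1	het	0.2109467881
A0200	2	hom	1.972978656
A0201	0	hom	-1.452846029
A0202	1	het	0.9602264052
A0203	0	hom	-0.5686628112
A0204	1	het	1.110233677
A0205	1	het	0.1770785122
A0206	2	hom	1.534300744
A0207	0	hom	-0.3985052285
A0208	2	hom	0.9741350738
A0209	2	hom	0.6524714592
A0210	1	het	-0.1014535874
A0211	1	het	0.7188911069
A0212	0	hom	0.1723714307
A0213	0	hom	-0.8431711783
A0214	1	het	0.01684907013
A0215	1	het	0.1467887808
A0216	0	hom	-1.358296666
A0217	2	hom	1.869995142
A0218	1	het	0.5878505061
A0219	1	het	-0.1728990267
A0220	0	hom	-0.5692669515
A0221	2	hom	0.6417326087
A0222	1	het	0.2984180861
A0223	0	hom	0.07131236268
A0224	1	het	0.721992796
A0225	1	het	-0.414314631
A0226	0	hom	0.2206480944
A0227	0	hom	0.1799018659
A0228	0	hom	-0.5195691846
A0229	0	hom	-0.4366280277
A0230	1	het	-1.184682369
A0231	0	hom	-0.08666775888
A0232	0	hom	-0.3317942887
A0233	2	hom	0.817868419
A0234	0	hom	-1.167215432
A0235	1	het	0.1918941515
A0236	1	het	0.5706262157
A0237	0	hom	-1.219311415
A0238	0	hom	-0.004186277105
A0239	1	het	0.4979684432
A0240	1	het	0.8544666653
A0241	2	hom	0.8027685945
A0242	0	hom	-1.092996096
A0243	1	het	-0.1925183572
A0244	0	hom	0.04830632952
A0245	0	hom	-0.4679972907
A0246	1	het	0.2527794321
A0247	1	het	-0.4011645797
A0248	1	het	0.4941475215
A0249	0	hom	-0.6199099734
A0250	2	hom	1.167399635
A0251	0	hom	-0.1655428312
A0252	0	hom	-0.3035404056
A0253	0	hom	-0.8637205896
A0254	1	het	-0.2378206442
A0255	0	hom	-0.2688449335
A0256	2	hom	0.8949846272
A0257	1	het	0.998015139
A0258	1	het	0.4310174969
A0259	0	hom	-1.333611109
A0260	1	het	0.2980077622
A0261	2	hom	0.537589449
A0262	1	het	0.5257305156
A0263	0	hom	-0.4238343415
A0264	0	hom	-0.6847837903
A0265	0	hom	0.5621442429
A0266	1	het	0.1662099091
A0267	2	hom	1.584641412
A0268	0	hom	-0.03790903009
A0269	1	het	1.262506867
A0270	0	hom	-0.3392470294
A0271	1	het	0.8507946356
A0272	1	het	0.1014937162
A0273	0	hom	-0.1323472074
A0274	0	hom	-0.8585482729
A0275	1	het	0.1855868585
A0276	1	het	-0.5343564592
A0277	0	hom	-0.1189373612
A0278	2	hom	1.634110534
A0279	1	het	-0.7436267703
A0280	0	hom	0.2657812283
A0281	1	het	-0.3277869508
A0282	1	het	-0.1947710579
A0283	0	hom	-1.050437597
A0284	1	het	-0.04675442692
A0285	1	het	0.4522846534
A0286	1	het	0.008919800821
A0287	1	het	0.8350437709
A0288	1	het	-0.2673653871
A0289	1	het	0.2697530488
A0290	1	het	0.1812769745
A0291	2	hom	0.8784291186
A0292	0	hom	-0.7677465618
A0293	2	hom	0.5459366723
A0294	1	het	0.5924255986
A0295	2	hom	0.9788005219
A0296	1	het	0.2006557487
A0297	1	het	0.8799618012
A0298	2	hom	0.9766316502
A0299	0	hom	-0.3981627631
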