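# nucmux constraint set, chain_length=147
# SYNTHETIC stand-in fixture: 28 midframes / 14 binding sites on an
# ideal left-handed superhelix (radius 41.9 A, pitch 25.4 A, 1.75 turns,
# helical repeat 10.3 bp), generated by nucmux.constraints.ideal_superhelix_constraints().
step_index	site_id	ox	oy	oz	r00	r01	r02	r10	r11	r12	r20	r21	r22
4	0	29.627774131716333	-29.627774131716347	-22.224999999999998	0.3588209768916365	0.6130732676174064	-0.7038385291211671	-0.46893936000269587	-0.5335796112716591	-0.7038385291211666	-0.8070584756898311	0.5826096179845485	0.09603462838531172
7	0	21.708071141112473	-35.83810328871214	-21.25164233576642	0.3918377801972058	-0.3487549100809081	-0.8513713447753477	-0.5034907169992963	0.693219239814666	-0.5156977636623132	0.770039123620132	0.630727435779699	0.09603462838531171
14	1	-0.7205816224936977	-41.893803385767264	-18.980474452554745	-0.094142213581204	0.02555239762909617	-0.9952307866004927	-0.4264299048822954	-0.9043586150795583	0.01711816443020546	-0.8996081257103603	0.4260077115578867	0.09603462838531171
17	1	-10.689758561494143	-40.51344297757181	-18.007116788321166	-0.1349527624210415	0.23558253460755232	-0.9624388922434564	-0.7543962784669374	0.6053077945864829	0.25394631095584697	0.6423970788773602	0.7603310747304295	0.09603462838531171
25	2	-32.82282552573919	-26.04365804772601	-15.411496350364965	-0.6369034150775233	-0.45996914243069764	-0.6186941311133933	-0.4262394079768138	-0.4586120853301153	0.7797402915565788	-0.6423970788773588	0.7603310747304308	0.09603462838531172
28	2	-38.08631992410511	-17.465458328904912	-14.438138686131387	-0.3528519665932694	0.8386567265279602	-0.4149100923340723	-0.25729498601246387	0.33937048301615647	0.9047800646733032	0.8996081257103608	0.42600771155788575	0.09603462838531172
35	3	-41.53629520725668	5.508736738638505	-12.166970802919707	-0.6183882077701123	-0.7749001080698585	0.13086575947966594	0.1569578688221992	0.041385073010543325	0.9867378087145061	-0.7700391236201324	0.6307274357796983	0.09603462838531172
38	3	-39.02446825191011	15.254536297628324	-11.19361313868613	-0.5734941765866343	0.7346971090110781	0.3623873444699502	0.14057398848442965	-0.34754307796684236	0.9270667520297083	0.8070584756898336	0.5826096179845449	0.09603462838531171
45	4	-24.89946863615791	33.699057281131594	-8.922445255474452	-0.21894270956071019	-0.5578297610883679	0.8005560864638461	0.43788513482238156	0.6770297675324172	0.5915127239346472	-0.8719637025884732	0.4800590083719874	0.09603462838531172
48	4	-16.145330364118674	38.664432071782294	-7.949087591240876	-0.3398437768839514	0.202086010435766	0.918513718841154	0.6416964441887227	-0.6641654726527575	0.3835490821935161	0.6875550020389645	0.7197537560319464	0.09603462838531172
56	5	10.22455247006265	40.63334255001594	-5.353467153284671	0.25131038827417873	0.07115933054626078	0.9652872310466402	0.7635425884392221	0.5983350264779151	-0.24289485735438196	-0.5948493963895521	0.7980799118922121	0.09603462838531172
59	5	19.618995190745494	37.02303374529841	-4.380109489051095	0.09546218126579725	-0.4661871834873982	0.8795205977690704	0.3705195974419761	-0.8034266361408513	-0.46606959593051345	0.9239059475181508	0.37037163807651774	0.09603462838531172
66	6	36.326432426369216	20.880620373265515	-2.1089416058394157	0.6243402314437184	0.6034424483566942	0.49604081175048753	0.2776196952440727	0.42214504803891245	-0.8629721103423983	-0.7301551754342308	0.6764989060874398	0.09603462838531172
69	6	40.257682594580956	11.615893943815653	-1.1355839416058393	0.49133792583564884	-0.8260992401507757	0.275947618322452	0.22622779883326183	-0.1849073306875523	-0.9563630388576617	0.8410755172221932	0.532324454144571	0.09603462838531172
76	7	40.257682594580956	-11.615893943815653	1.1355839416058393	0.4913379258356463	0.8260992401507773	-0.275947618322452	-0.22622779883326125	-0.18490733068755305	-0.9563630388576617	-0.841075517222195	0.5323244541445683	0.09603462838531172
79	7	36.326432426369216	-20.880620373265515	2.1089416058394157	0.6243402314437203	-0.6034424483566923	-0.49604081175048753	-0.27761969524407404	0.4221450480389117	-0.8629721103423983	0.7301551754342287	0.6764989060874421	0.09603462838531172
86	8	19.618995190745494	-37.02303374529841	4.380109489051095	0.09546218126579245	0.4661871834873992	-0.8795205977690704	-0.37051959744196783	-0.8034266361408552	-0.46606959593051345	-0.9239059475181547	0.3703716380765082	0.09603462838531172
89	8	10.22455247006265	-40.63334255001594	5.353467153284671	0.25131038827417873	-0.07115933054626085	-0.9652872310466402	-0.7635425884392218	0.5983350264779154	-0.24289485735438196	0.5948493963895524	0.7980799118922118	0.09603462838531172
97	9	-16.145330364118674	-38.664432071782294	7.949087591240876	-0.33984377688394934	-0.20208601043576943	-0.918513718841154	-0.6416964441887159	-0.664165472652764	0.3835490821935161	-0.6875550020389718	0.7197537560319391	0.09603462838531172
100	9	-24.89946863615791	-33.699057281131594	8.922445255474452	-0.218942709560712	0.5578297610883671	-0.8005560864638461	-0.4378851348223837	0.6770297675324157	0.5915127239346472	0.8719637025884717	0.4800590083719902	0.09603462838531172
107	10	-39.02446825191011	-15.254536297628324	11.19361313868613	-0.5734941765866319	-0.7346971090110799	-0.3623873444699502	-0.14057398848442848	-0.34754307796684286	0.9270667520297083	-0.8070584756898355	0.5826096179845422	0.09603462838531171
110	10	-41.53629520725668	-5.508736738638505	12.166970802919707	-0.6183882077701148	0.7749001080698565	-0.13086575947966594	-0.15695786882219936	0.04138507301054281	0.9867378087145061	0.7700391236201304	0.6307274357797007	0.09603462838531172
117	11	-38.08631992410511	17.465458328904912	14.438138686131387	-0.3528519665932668	-0.8386567265279613	0.4149100923340723	0.2572949860124628	0.33937048301615724	0.9047800646733032	-0.8996081257103621	0.4260077115578829	0.09603462838531172
120	11	-32.82282552573919	26.04365804772601	15.411496350364965	-0.6369034150775224	0.459969142430699	0.6186941311133933	0.42623940797681276	-0.45861208533011627	0.7797402915565788	0.6423970788773603	0.7603310747304293	0.09603462838531172
128	12	-10.689758561494143	40.51344297757181	18.007116788321166	-0.1349527624210418	-0.23558253460755219	0.9624388922434564	0.754396278466938	0.6053077945864819	0.25394631095584697	-0.6423970788773593	0.7603310747304303	0.09603462838531171
131	12	-0.7205816224936977	41.893803385767264	18.980474452554745	-0.09414221358120414	-0.025552397629095634	0.9952307866004927	0.42642990488229027	-0.9043586150795608	0.01711816443020546	0.8996081257103627	0.42600771155788164	0.09603462838531171
138	13	21.708071141112473	35.83810328871214	21.25164233576642	0.39183778019720217	0.3487549100809122	0.8513713447753477	0.503490716999289	0.6932192398146714	-0.5156977636623132	-0.7700391236201386	0.6307274357796909	0.09603462838531171
141	13	29.627774131716333	29.627774131716347	22.224999999999998	0.3588209768916396	-0.6130732676174045	0.7038385291211671	0.46893936000269865	-0.5335796112716567	-0.7038385291211666	0.8070584756898281	0.5826096179845526	0.09603462838531172
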