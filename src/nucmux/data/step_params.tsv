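# Dinucleotide step parameters, hybrid-style parametrization:
# intrinsic values from a protein-DNA crystal survey, stiffnesses
# (diagonal force constants + cross-couplings) from atomistic-MD-derived
# literature values. Order: shift, slide, rise [Angstrom]; tilt, roll,
# twist [degrees]; stiffness in kT_room per squared unit.
# 10 distinct steps; the other 6 follow by the inversion transformation.
step	row	shift	slide	rise	tilt	roll	twist
AA	q0	-0.03	-0.08	3.27	-1.4	0.7	35.1
AA	Q0	5.5	0.0	0.0	0.149248115565993	0.0	0.0
AA	Q1	0.0	4.5	0.0	0.0	0.0	0.2078460969082653
AA	Q2	0.0	0.0	20.0	0.0	0.19364916731037085	0.21908902300206645
AA	Q3	0.149248115565993	0.0	0.0	0.045	0.0	0.0
AA	Q4	0.0	0.0	0.19364916731037085	0.0	0.03	-0.014849242404917497
AA	Q5	0.0	0.2078460969082653	0.21908902300206645	0.0	-0.014849242404917497	0.06
AC	q0	0.13	-0.58	3.36	-0.1	0.7	31.5
AC	Q0	6.2	0.0	0.0	0.16365818036383029	0.0	0.0
AC	Q1	0.0	4.0	0.0	0.0	0.0	0.1876166303929372
AC	Q2	0.0	0.0	21.0	0.0	0.1984313483298443	0.2149418526020468
AC	Q3	0.16365818036383029	0.0	0.0	0.048	0.0	0.0
AC	Q4	0.0	0.0	0.1984313483298443	0.0	0.03	-0.014217067208112931
AC	Q5	0.0	0.1876166303929372	0.2149418526020468	0.0	-0.014217067208112931	0.055
AG	q0	0.09	-0.25	3.34	-1.7	4.5	31.9
AG	Q0	5.0	0.0	0.0	0.1374772708486752	0.0	0.0
AG	Q1	0.0	3.6	0.0	0.0	0.0	0.16970562748477144
AG	Q2	0.0	0.0	18.0	0.0	0.16770509831248423	0.18973665961010278
AG	Q3	0.1374772708486752	0.0	0.0	0.042	0.0	0.0
AG	Q4	0.0	0.0	0.16770509831248423	0.0	0.025	-0.012374368670764583
AG	Q5	0.0	0.16970562748477144	0.18973665961010278	0.0	-0.012374368670764583	0.05
AT	q0	0.0	-0.59	3.31	0.0	1.1	29.3
AT	Q0	6.5	0.0	0.0	0.1710263137648707	0.0	0.0
AT	Q1	0.0	5.0	0.0	0.0	0.0	0.23664319132398465
AT	Q2	0.0	0.0	22.0	0.0	0.22248595461286988	0.24819347291981717
AT	Q3	0.1710263137648707	0.0	0.0	0.05	0.0	0.0
AT	Q4	0.0	0.0	0.22248595461286988	0.0	0.036	-0.017569860557215586
AT	Q5	0.0	0.23664319132398465	0.24819347291981717	0.0	-0.017569860557215586	0.07
CA	q0	0.09	0.53	3.33	0.5	4.7	34.5
CA	Q0	4.2	0.0	0.0	0.11502173707608489	0.0	0.0
CA	Q1	0.0	2.2	0.0	0.0	0.0	0.11099549540409288
CA	Q2	0.0	0.0	15.0	0.0	0.1224744871391589	0.1449137674618944
CA	Q3	0.11502173707608489	0.0	0.0	0.035	0.0	0.0
CA	Q4	0.0	0.0	0.1224744871391589	0.0	0.016	-0.008282511696339463
CA	Q5	0.0	0.11099549540409288	0.1449137674618944	0.0	-0.008282511696339463	0.035
CC	q0	0.05	-0.22	3.42	-0.1	3.6	33.7
CC	Q0	5.5	0.0	0.0	0.1407124727947029	0.0	0.0
CC	Q1	0.0	4.2	0.0	0.0	0.0	0.1795995545651492
CC	Q2	0.0	0.0	19.0	0.0	0.17571283390805578	0.19099738218101317
CC	Q3	0.1407124727947029	0.0	0.0	0.04	0.0	0.0
CC	Q4	0.0	0.0	0.17571283390805578	0.0	0.026	-0.012364465212858985
CC	Q5	0.0	0.1795995545651492	0.19099738218101317	0.0	-0.012364465212858985	0.048
CG	q0	0.0	0.41	3.39	0.0	5.4	29.8
CG	Q0	4.5	0.0	0.0	0.12405643876881198	0.0	0.0
CG	Q1	0.0	2.8	0.0	0.0	0.0	0.1338656042454521
CG	Q2	0.0	0.0	16.0	0.0	0.1414213562373095	0.16000000000000003
CG	Q3	0.12405643876881198	0.0	0.0	0.038	0.0	0.0
CG	Q4	0.0	0.0	0.1414213562373095	0.0	0.02	-0.009899494936611665
CG	Q5	0.0	0.1338656042454521	0.16000000000000003	0.0	-0.009899494936611665	0.04
GA	q0	-0.28	0.09	3.37	-1.5	1.9	36.9
GA	Q0	5.8	0.0	0.0	0.15155197128378106	0.0	0.0
GA	Q1	0.0	4.0	0.0	0.0	0.0	0.1876166303929372
GA	Q2	0.0	0.0	20.0	0.0	0.18708286933869708	0.20976176963403034
GA	Q3	0.15155197128378106	0.0	0.0	0.044	0.0	0.0
GA	Q4	0.0	0.0	0.18708286933869708	0.0	0.028	-0.013734991809244007
GA	Q5	0.0	0.1876166303929372	0.20976176963403034	0.0	-0.013734991809244007	0.055
GC	q0	0.0	-0.38	3.4	0.0	0.3	40.0
GC	Q0	6.8	0.0	0.0	0.17839282496782208	0.0	0.0
GC	Q1	0.0	3.5	0.0	0.0	0.0	0.18022208521710098
GC	Q2	0.0	0.0	23.0	0.0	0.22107690969434143	0.2309978354876946
GC	Q3	0.17839282496782208	0.0	0.0	0.052	0.0	0.0
GC	Q4	0.0	0.0	0.22107690969434143	0.0	0.034	-0.015542522317822162
GC	Q5	0.0	0.18022208521710098	0.2309978354876946	0.0	-0.015542522317822162	0.058
TA	q0	0.0	0.05	3.42	0.0	3.3	37.8
TA	Q0	4.0	0.0	0.0	0.1073312629199899	0.0	0.0
TA	Q1	0.0	2.0	0.0	0.0	0.0	0.09797958971132713
TA	Q2	0.0	0.0	14.0	0.0	0.11067971810589328	0.1296148139681572
TA	Q3	0.1073312629199899	0.0	0.0	0.032	0.0	0.0
TA	Q4	0.0	0.0	0.11067971810589328	0.0	0.014	-0.007172865536171719
TA	Q5	0.0	0.09797958971132713	0.1296148139681572	0.0	-0.007172865536171719	0.03
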