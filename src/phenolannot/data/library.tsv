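peak	rt	mz	ppm_printed	formula	formula_printed	fragments	base_peak	name	compound_class
1	1.84	169.0138	0.6	C7H6O5	C7H6O5	125	125	Gallic acid	phenolic_acid_derivative
2	4.51	355.0661	1.1	C15H16O10	C15H16O10	337;313;209;191;163;147;129	191	O-Coumaroylgalactaric acid	phenolic_acid_derivative
3	4.91	385.0766	1.3	C16H18O11	C16H18O11	209;191;173;147	191	O-Feruloylgalactaric acid	phenolic_acid_derivative
4	5.17	183.0285	4.4	C8H8O5	C8H8O5	168;124	168	Methyl gallate	phenolic_acid_derivative
5	5.92	951.0703	3.9	C41H28O27	C41H28O27	933;915;763;633;463;461;443;301;275;273;169	301	Galloyl-DHHDP-HHDP-glucose	ellagitannin
6	6.09	633.0710	2.8	C27H22O18	C27H22O18	463;301;275;249;169	301	Galloyl-HHDP-glucose	ellagitannin
7	6.56	953.0888	0.8	C41H30O27	C41H30O27	935;909;801;783;765;633;481;463;337;319;301;293;275;249;169	301	Galloyl-Che-HHDP-glucose Isomer I	ellagitannin
8	6.56	635.0866	2.8	C27H24O18	C27H24O18	465;313;271;221;211;193;169;125	169	Trigalloyl-glucose	gallotannin
9	6.92	163.0389	3.7	C9H8O3	C9H8O3	119	119	p-Coumaric acid	phenolic_acid_derivative
10	6.98	625.1368	5.9	C27H30O17	C27H30O17	301;300;271;255;243;179;151	300	Quercetin 3-O-glucosyl-glucoside	flavonoid_O_glycoside
11	7.18	197.0445	2.5	C9H10O5	C9H10O5	169;168;125;124	169	Ethyl gallate	phenolic_acid_derivative
12	7.24	925.0983	3.6	C40H30O26	C40H30O26	755;615;605;453;435;309;301;275;249;247;169	301	Phyllanthusiin C Isomer	ellagitannin
13	7.55	433.0410	0.7	C19H14O12	C19H14O12	301;300	301	Ellagic acid O-xyloside	phenolic_acid_derivative
14	7.67	595.1321	3.7	C26H28O16	C26H28O16	301;300;271;255;243;179;151	300	Quercetin 3-O-xylosyl-glucoside	flavonoid_O_glycoside
15	7.84	609.1427	4.8	C27H30O16	C27H30O16	301;300;271;255;243;179;151	300	Quercetin 3-O-rhamnosyl-glucoside	flavonoid_O_glycoside
16	7.87	447.0585	4.7	C20H16O12	C20H16O12	301;300	300	Ellagic acid O-rhamnoside	phenolic_acid_derivative
17	7.96	953.0904	0.8	C41H30O27	C41H30O27	935;909;801;783;765;633;481;463;337;319;301;293;275;249;169	301	Galloyl-Che-HHDP-glucose Isomer II	ellagitannin
18	8.01	300.9972	4.0	C14H6O8	C14H6O8	283;245;229;201;185;173;145	283	Ellagic acid	phenolic_acid_derivative
19	8.39	785.0847	1.3	C34H26O22	C34H26O22	633;615;463;301;275;249;169	633	Digalloyl-HHDP-glucose	ellagitannin
20	8.39	985.1155	0.3	C42H34O28	C42H34O28	783;633;463;351;301;169	301	Methyl neochebulagate Isomer	ellagitannin
21	8.62	463.0890	2.8	C21H20O12	C21H20O12	301;300;271;255;243;179;151	300	Quercetin 3-O-glucoside Isomer I	flavonoid_O_glycoside
22	8.73	857.1077	3.3	C37H30O24	C37H30O24	825;655;615;463;301;275;169	301	Excoecariphenol C Isomer	ellagitannin
23	8.73	787.0977	2.2	C34H28O22	C34H28O22	635;617;593;465;449;169	169	Tetragalloyl-glucose	gallotannin
24	8.76	593.1528	3.7	C27H30O15	C27H30O15	285;284;255;227;151	284	Kaempferol 3-O-rhamnosyl-glucoside	flavonoid_O_glycoside
25	8.87	579.1376	4.0	C26H28O15	C26H28O15	285;284;255;227;151	284	Kaempferol 3-O-xylosyl-glucoside	flavonoid_O_glycoside
26	8.87	463.0898	4.5	C21H20O12	C21H20O12	301;300;271;255;243;179;151	300	Quercetin 3-O-glucoside Isomer II	flavonoid_O_glycoside
27	8.93	491.0852	5.3	C22H20O13	C22H20O13	313;298;285;270	313	Di-O-Methyl ellagic acid O-glucoside	phenolic_acid_derivative
28	9.41	579.1350	0.0	C26H28O15	C26H28O15	301;300;271;255;243;179;151	300	Quercetin 3-O-rhamnosyl-xyloside	flavonoid_O_glycoside
29	9.61	433.0765	1.4	C20H18O11	C20H18O11	300;301;271;255;243;179;151	300	Quercetin 3-O-xyloside	flavonoid_O_glycoside
30	9.70	447.0935	1.8	C21H20O11	C21H20O11	285;284;255;227;151	284	Kaempferol 3-O-glucoside Isomer I	flavonoid_O_glycoside
31	9.95	603.0945	6.8	C27H24O16	C27H24O16	451;433;301;275;169	169	Galloyl-HHDP-dideoxyglucose	ellagitannin
32	10.15	603.1013	4.5	C27H24O16	C27H24O16	451;433;211;169	169	Trigalloyl-dideoxyglucose	gallotannin
33	10.24	447.0914	2.9	C21H20O11	C21H20O11	285;284;255;227;151	284	Kaempferol 3-O-glucoside Isomer II	flavonoid_O_glycoside
34	10.61	563.1431	5.3	C26H28O14	C26H27O14	285;284;255;227;151	284	Kaempferol 3-O-rhamnosyl-xyloside	flavonoid_O_glycoside
35	10.69	417.0836	3.4	C20H18O10	C20H18O10	285;284;255;227;151	284	Kaempferol 3-O-xyloside	flavonoid_O_glycoside
36	10.78	461.0736	3.5	C21H18O12	C21H18O12	315;300	300	Methylellagic acid O-rhamnoside	phenolic_acid_derivative
37	11.01	951.0743	0.3	C41H28O27	C41H28O27	907;781;737;649;615;605;497;479;435;335;301;291;275;273;247;169	301	Phyllanthusiin A Isomer	ellagitannin
38	12.10	937.0962	1.6	C41H30O26	C41H30O26	785;767;635;615;465;301;275;249;169	301	Trigalloyl-HHDP-glucose	ellagitannin
39	12.29	923.0801	1.1	C40H28O26	C40H28O26	879;825;655;621;615;577;523;451;407;301;275;249;169	301	Phyllanthusiin U Isomer	ellagitannin
40	14.00	301.0334	4.7	C15H10O7	C15H10O7	273;257;229;179;151;121;107	151	Quercetin	flavonoid_O_glycoside
41	14.91	477.1018	3.1	C22H22O12	C22H22O12	314;315	314	Methylquercetin 3-O-glucoside	flavonoid_O_glycoside
42	16.91	285.0399	0.0	C15H10O6	C15H10O6	267;255;243;239;229;227;185;163;151	151	Kaempferol	flavonoid_O_glycoside
43	18.14	763.1154	0.9	C36H28O19	C36H28O19	615;593;463;445;301;275;249;169	301	Galloyl-Cinnamoyl-HHDP-glucose	ellagitannin
44	19.04	343.0450	1.2	C17H12O8	C17H12O8	328;313;298;285;270;257;242	298	Tri-O-methylellagic acid	phenolic_acid_derivative
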