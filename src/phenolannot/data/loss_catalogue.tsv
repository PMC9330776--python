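name	formula	mass	kind	evidence	tol
water	H2O	18.010565	neutral_loss	generic	
carbon_monoxide	CO	27.994915	neutral_loss	generic	
carbon_dioxide	CO2	43.989829	neutral_loss	carboxyl	
ketene	C2H2O	42.010565	neutral_loss	generic	
formaldehyde	CH2O	30.010565	neutral_loss	generic	
formic_acid	CH2O2	46.005479	neutral_loss	generic	
glyoxal	C2H2O2	58.005479	neutral_loss	generic	
methanol	CH4O	32.026215	neutral_loss	generic	
ethene	C2H4	28.0313	neutral_loss	generic	
propenone	C3H2O	54.010565	neutral_loss	dhhdp_cascade	
methyl_radical	CH3	15.023475	radical_loss	methyl	
ethyl_radical	C2H5	29.039125	radical_loss	methyl	
coumaric_acid	C9H8O3	164.047344	neutral_loss	coumaroyl	
coumaroyl	C9H6O2	146.036779	neutral_loss	coumaroyl	
ferulic_acid	C10H10O4	194.057909	neutral_loss	feruloyl	
feruloyl	C10H8O3	176.047344	neutral_loss	feruloyl	
cinnamic_acid	C9H8O2	148.052429	neutral_loss	cinnamoyl	
cinnamoyl	C9H6O	130.041865	neutral_loss	cinnamoyl	
pentose	C5H8O4	132.042259	neutral_loss	sugar:pentose	
pentosyl_radical	C5H9O4	133.050084	radical_loss	sugar:pentose:radical	
deoxyhexose	C6H10O4	146.057909	neutral_loss	sugar:deoxyhexose	
deoxyhexosyl_radical	C6H11O4	147.065734	radical_loss	sugar:deoxyhexose:radical	
hexose	C6H10O5	162.052823	neutral_loss	sugar:hexose	
hexosyl_radical	C6H11O5	163.060648	radical_loss	sugar:hexose:radical	
rhamnosyl_xyloside	C11H18O8	278.100168	neutral_loss	sugar:rhamnosyl-xyloside	
rhamnosyl_xylosyl_radical	C11H19O8	279.107993	radical_loss	sugar:rhamnosyl-xyloside:radical	
xylosyl_glucoside	C11H18O9	294.095082	neutral_loss	sugar:xylosyl-glucoside	
xylosyl_glucosyl_radical	C11H19O9	295.102907	radical_loss	sugar:xylosyl-glucoside:radical	
rhamnosyl_glucoside	C12H20O9	308.110732	neutral_loss	sugar:rhamnosyl-glucoside	
rhamnosyl_glucosyl_radical	C12H21O9	309.118557	radical_loss	sugar:rhamnosyl-glucoside:radical	
glucosyl_glucoside	C12H20O10	324.105647	neutral_loss	sugar:glucosyl-glucoside	
glucosyl_glucosyl_radical	C12H21O10	325.113472	radical_loss	sugar:glucosyl-glucoside:radical	
galloyl	C7H4O4	152.010959	neutral_loss	galloyl	
gallic_acid	C7H6O5	170.021523	neutral_loss	galloyl	
hhdp	C14H6O8	302.006267	neutral_loss	HHDP	
dhhdp_residue	C14H6O9	318.001182	neutral_loss	DHHDP	
chebuloyl_residue	C14H8O9	320.016832	neutral_loss	Che	
phyllanthusiin_residue	C13H10O9	310.032482	neutral_loss	oxidized_congener	
phyllanthusiin_residue_dehydro	C13H8O9	308.016832	neutral_loss	oxidized_congener	
methylchebulate_residue	C15H12O10	352.043047	neutral_loss	oxidized_congener	
galloyl_methylacetate		242.043	neutral_loss	galloyl_methylacetate	0.05
gallate_anion	C7H5O5	169.013698	diagnostic_fragment	galloyl	
gallate_decarboxylated	C6H5O3	125.023869	diagnostic_fragment	phenolic_acid	
coumarate_anion	C9H7O3	163.039519	diagnostic_fragment	phenolic_acid	
coumarate_decarboxylated	C8H7O	119.04969	diagnostic_fragment	phenolic_acid	
galactarate_anion	C6H9O8	209.029742	diagnostic_fragment	phenolic_acid	
galactarate_dehydrated	C6H7O7	191.019178	diagnostic_fragment	phenolic_acid	
galloylglycoside_rda	C9H7O6	211.024263	diagnostic_fragment	gallotannin_rda	
urolithin_anion	C13H7O7	275.019178	diagnostic_fragment	HHDP	
ellagate_anion	C14H5O8	300.998442	diagnostic_fragment	HHDP	
ellagate_radical_anion	C14H4O8	299.990617	diagnostic_fragment	ellagic_derivative	
methylellagate_anion	C15H7O8	315.014092	diagnostic_fragment	ellagic_derivative	
dimethylellagate_radical_anion	C16H8O8	328.021917	diagnostic_fragment	ellagic_derivative	
methylellagate_core_anion	C15H5O8	312.998442	diagnostic_fragment	ellagic_derivative	
ellagate_core_anion	C14H2O8	297.974967	diagnostic_fragment	ellagic_derivative	
phyllanthusiin_anion	C13H9O9	309.024657	diagnostic_fragment	oxidized_congener	
methylchebulate_anion	C15H11O10	351.035222	diagnostic_fragment	oxidized_congener	
chebulate_dehydrated_anion	C14H9O10	337.019571	diagnostic_fragment	Che	
chebulate_didehydrated_anion	C14H7O9	319.009007	diagnostic_fragment	Che	
chebulate_decarboxylated_anion	C13H9O8	293.029742	diagnostic_fragment	Che	
ellagitannin_249	C12H9O6	249.039913	diagnostic_fragment	tannin_secondary	
ellagitannin_247	C12H7O6	247.024263	diagnostic_fragment	tannin_secondary	
quercetin_anion	C15H9O7	301.034828	diagnostic_fragment	aglycone:quercetin	
quercetin_radical_anion	C15H8O7	300.027003	diagnostic_fragment	aglycone:quercetin:radical	
kaempferol_anion	C15H9O6	285.039913	diagnostic_fragment	aglycone:kaempferol	
kaempferol_radical_anion	C15H8O6	284.032088	diagnostic_fragment	aglycone:kaempferol:radical	
methylquercetin_anion	C16H11O7	315.050478	diagnostic_fragment	aglycone:methylquercetin	
methylquercetin_radical_anion	C16H10O7	314.042653	diagnostic_fragment	aglycone:methylquercetin:radical	
flavonoid_151	C7H3O4	151.003134	diagnostic_fragment	flavonoid_secondary	
flavonoid_179	C8H3O5	178.998048	diagnostic_fragment	flavonoid_secondary	
flavonoid_227	C13H7O4	227.034434	diagnostic_fragment	flavonoid_secondary	
flavonoid_243	C13H7O5	243.029348	diagnostic_fragment	flavonoid_secondary	
flavonoid_255	C14H7O5	255.029348	diagnostic_fragment	flavonoid_secondary	
flavonoid_271	C14H7O6	271.024263	diagnostic_fragment	flavonoid_secondary	
flavonoid_273	C14H9O6	273.039913	diagnostic_fragment	flavonoid_secondary	
flavonoid_121	C7H5O2	121.028954	diagnostic_fragment	flavonoid_secondary	
flavonoid_107	C6H3O2	107.013304	diagnostic_fragment	flavonoid_secondary	
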