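panel	label	k	n	printed_percent	decimals	note
lung_glia_class_census	NMG	6949	9109	76	0
lung_glia_class_census	MG	2025	9109	22	0
lung_glia_class_census	SG	107	9109	1.17	2
lung_glia_class_census	TGNS	28	9109	0.31	2
neb_contact	basal	94	151	62	0
neb_contact	intraepithelial	24	151	16	0	companion text prints 18% for the same 24/151
neb_contact	none	33	151	22	0
neb_contact	any_contact	118	151	78	0
gfap_by_class	NMG	143	359	40	0	companion text prints 40% (142/369); tallies disagree, legend values carried
gfap_by_class	MG	4	96	4	0
gfap_by_class	SG	59	128	46	0
gfap_by_class	TGNS	1	16	6	0
gfra3_by_class	NMG	447	475	94	0
gfra3_by_class	MG	7	218	3.2	1
gfra3_by_class	SG	48	144	33.3	1
th_association	MG	247	267	92.5	1
th_association	NMG_airway	1081	1623	66.6	1	companion text prints 67% (1087/1623); tallies disagree, both carried
th_association	NMG_airway_alt	1087	1623	67	0	main-text variant of the airway tally
th_association	vein	83	83	100	0
bladder_mbp	lamina_propria	0	136	0	0
bladder_mbp	detrusor	41	375	11	0
bladder_markers	s100_lamina	43	62	69	0
bladder_markers	s100_detrusor	113	190	59	0
bladder_markers	gfap_lamina	1	46	2	0
bladder_markers	gfap_detrusor	13	210	6	0
bladder_markers	gfra3_lamina	78	83	94	0
bladder_markers	gfra3_detrusor	69	186	37	0
morphology	unipolar_vein	3	84		0	counts reported without a percentage
morphology	bipolar_vein	45	84		0	counts reported without a percentage
morphology	multipolar_vein	36	84		0	counts reported without a percentage
morphology	unipolar_airway	1	115		0	counts reported without a percentage
morphology	bipolar_airway	60	115		0	counts reported without a percentage
morphology	multipolar_airway	54	115		0	counts reported without a percentage
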