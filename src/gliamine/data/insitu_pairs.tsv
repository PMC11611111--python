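panel	label_1	label_2	p_bound
neb_contact	basal	intraepithelial	0.0001
neb_contact	basal	none	0.0001
gfap_by_class	NMG	MG	0.0001
gfap_by_class	NMG	TGNS	0.01
gfap_by_class	MG	SG	0.0001
gfap_by_class	SG	TGNS	0.005
gfra3_by_class	NMG	MG	0.0001
gfra3_by_class	NMG	SG	0.0001
gfra3_by_class	MG	SG	0.0001
th_association	MG	NMG_airway	0.0001
th_association	NMG_airway	vein	0.0001
bladder_mbp	lamina_propria	detrusor	0.0001
bladder_markers	gfra3_lamina	gfra3_detrusor	0.0001
morphology	unipolar_airway	bipolar_airway	0.0001
morphology	unipolar_airway	multipolar_airway	0.0001
morphology	unipolar_vein	bipolar_vein	0.0001
morphology	unipolar_vein	multipolar_vein	0.0001
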