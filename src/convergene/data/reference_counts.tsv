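group	name_a	n_a	name_b	n_b	k	rf_printed	pct_printed	pct_base	k_alt
overall	PEG	12478	FastEvolvingUnion	6106	3196	0.8
peg_category	PEG	12478	CAC	1035	530		51.2	b
peg_category	PEG	12478	HARs	2657	1646		62.0	b
peg_category	PEG	12478	EPS	3053	1435		47.0	b
tissue	BoneMarrow	85	CAC	1035	10	2.3
tissue	BoneMarrow	85	HARs	2657	2
tissue	BoneMarrow	85	EPS	3053	8
tissue	BoneMarrow	85	FastEvolvingUnion	6106	18		21.2	a
tissue	CerebralCortex	318	CAC	1035	10
tissue	CerebralCortex	318	HARs	2657	85	2.0
tissue	CerebralCortex	318	EPS	3053	31
tissue	CerebralCortex	318	FastEvolvingUnion	6106	110		34.6	a
tissue	Placenta	86	CAC	1035	7	1.6
tissue	Placenta	86	HARs	2657	10
tissue	Placenta	86	EPS	3053	15
tissue	Placenta	86	FastEvolvingUnion	6106	28		32.5	a	30
tissue	SalivaryGland	45	CAC	1035	6	2.6
tissue	SalivaryGland	45	HARs	2657	1
tissue	SalivaryGland	45	EPS	3053	5
tissue	SalivaryGland	45	FastEvolvingUnion	6106	11		24.4	a
tissue	ThyroidGland	23	CAC	1035	1
tissue	ThyroidGland	23	HARs	2657	8	2.6
tissue	ThyroidGland	23	EPS	3053	1
tissue	ThyroidGland	23	FastEvolvingUnion	6106	9		39.1	a
phenotype	Preeclampsia	896	CAC	1035	44
phenotype	Preeclampsia	896	HARs	2657	141	1.2
phenotype	Preeclampsia	896	EPS	3053	100
phenotype	Preeclampsia	896	FastEvolvingUnion	6106	255		28.5	a
phenotype	LED	443	CAC	1035	20
phenotype	LED	443	HARs	2657	75	1.3
phenotype	LED	443	EPS	3053	61
phenotype	LED	443	FastEvolvingUnion	6106	133	1.0	30.0	a
phenotype	PPROM	70	CAC	1035	5	1.4
phenotype	PPROM	70	HARs	2657	8
phenotype	PPROM	70	EPS	3053	8
phenotype	PPROM	70	FastEvolvingUnion	6106	16		22.8	a
phenotype	sPTB	44	CAC	1035	1
phenotype	sPTB	44	HARs	2657	9	1.6
phenotype	sPTB	44	EPS	3053	7	1.0
phenotype	sPTB	44	FastEvolvingUnion	6106	15	1.1	34.1	a
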