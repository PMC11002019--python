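gene	drug	interaction_type	categories
LAG3	relatlimab	inhibitor	approved;antineoplastic;immunotherapy
IDO1	epacadostat	inhibitor	antineoplastic;immunotherapy
TIGIT	tiragolumab	inhibitor	antineoplastic;immunotherapy
PDCD1	nivolumab	inhibitor	approved;antineoplastic;immunotherapy
PDCD1	pembrolizumab	inhibitor	approved;antineoplastic;immunotherapy
CTLA4	ipilimumab	inhibitor	approved;antineoplastic;immunotherapy
CD274	atezolizumab	inhibitor	approved;antineoplastic;immunotherapy
HAVCR2	sabatolimab	inhibitor	antineoplastic;immunotherapy
IL2RG	aldesleukin	agonist	approved;antineoplastic;immunotherapy
TNFRSF9	urelumab	agonist	antineoplastic;immunotherapy
BRAF	dabrafenib	inhibitor	approved;antineoplastic
BRAF	vemurafenib	inhibitor	approved;antineoplastic
NRAS	binimetinib	pathway inhibitor	approved;antineoplastic
KIT	imatinib	inhibitor	approved;antineoplastic
PTEN	everolimus	pathway inhibitor	approved;antineoplastic
TP53	idasanutlin	pathway modulator	antineoplastic
KRAS	sotorasib	inhibitor	approved;antineoplastic
PIK3CA	alpelisib	inhibitor	approved;antineoplastic
GZMB	serpinb9-mimetic	modulator	experimental
FOXP3	cyclophosphamide	depleting agent	approved;antineoplastic
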