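taxon	acronym	accession	isoform_label
Ailuropoda melanoleuca	Am	GL195116	isoform 1
Bos taurus	Bt	XM_864722, XP_869815	isoform 4
Canis familiaris	Cf	XP_542910	isoform 1
Callithrix jachus	Cj	ENSCJAP00000039547	isoform mu
Cavia porcellus	Cp	ENSCPOG00000024093	isoform mu
Dipodomys ordii	Do	ENSDOR00000002138	isoform mu
Equus caballus	Ec	XP_001495489	isoform 3
Felis catus	Fc	ENSFCAP00000002991	isoform mu
Gorilla gorilla	Go	ENSGGOP00000010403	isoform mu
Homo sapiens	Hs	ABM01872	isoform 5
Loxodonta africana	La	ENSLAF00000022779	isoform mu
Macropus eugenii	Me	ENSMEUG00000000861	no isoform
Microcebus murinus	Mu	ENSMICG00000006861	isoform mu
Monodelphis domestica	Md	XM_001380242	no isoform
Mus musculus	Mm	AJ567473	isoform mu
Myosotis lucifugus	Ml	ENSMLUG00000015515	isoform mu
Nomascus leucogenys	Nl	ID:ENSNLEG00000007689	isoform mu
Ornithorhyncus anatinus	Oa	XP_001516006,XM_001515956	no isoform
Oryctogalus cuniculus	Oc	ENSOCUG00000008024	isoform mu
Pan troglodytes	Pt	XP_001163910	isoform 5
Pongo abelii	Pa	XP_002830110	isoform 1
Rattus norvegicus	Rn	XM_218704	isoform mu
Sus scrofa	Ss	AK236942	isoform mu
Tarsius syrinchtae	Ts	ENSTSYG00000003146	isoform mu
Tursiops truncatus	Tt	GeneScaffold_412:9956:27593:1	isoform mu
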