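organism	common_name	acronym	enzyme_class	evidence	accession
Ailuropoda melanoleuca	giant panda	Am	SMO	predicted protein	GenBank:EFB25976
Anolis carolinensis	green anole	An	SMO	predicted protein	ID:ENSACAP00000000096
Bos taurus	cattle	Bt	SMO	protein	Swiss-Prot:Q865R1
Callithrix jacchus	pygmy marmoset	Cj	SMO	predicted protein	ID:ENSCJAP00000039556
Canis familiaris	dog	Cf	SMO	predicted protein	GenBank:XP_860548
Cavia porcellus	guinea pig	Cp	SMO	predicted protein	ID:ENSCPOP00000015071
Danio rerio	zebrafish	Dr	SMO	protein	Swiss-Prot:Q6NYY8
Dipodomys ordii	kangaroo rat	Do	SMO	predicted protein	ID:ENSDORP00000002003
Equus caballus	horse	Eq	SMO	predicted protein	GenBank:XP_001495419
Felis catus	cat	Fc	SMO	predicted protein	ID:ENSFCAP00000002991
Gallus gallus	chicken	Gg	SMO	predicted protein	GenBank:XP_420872
Gasterosteus aculeatus	three-spined stickleback	Ga	SMO	predicted protein	ID:ENSGACP00000023283
Gorilla gorilla	gorilla	Go	SMO	predicted protein	ID:ENSGGOP00000018695
Homo sapiens	human	Hs	SMO	protein	Swiss-Prot:Q99K82
Loxodonta africana	elephant	La	SMO	predicted protein	ID:ENSLAFP00000010450
Macaca fascicularis	macaque monkey	Mf	SMO	predicted protein	GeneBank:BAE88223
Macropus eugenii	wallaby	Me	SMO	predicted protein	ID:ENSMEUP00000000797
Microcebus murinus	lemur mouse	Mu	SMO	predicted protein	ID:ENSMICP00000006250
Monodelphis domestica	grey short-tailed opossum	Md	SMO	predicted protein	GenBank:XP_001380279
Mus musculus	house mouse	Mm	SMO	protein	Swiss-Prot:NP_663508
Myosotis lucifugus	microbat	Ml	SMO	predicted protein	ID:ENSMLUP00000014140
Nomascus leucogenys	gibbon	Nl	SMO	predicted protein	ID:ENSNLEG00000007689
Ornithorhyncus anatinus	platypus	Oa	SMO	predicted protein	GenBank:XP_001516006
Oryctogalus cuniculus	rabbit	Oc	SMO	predicted protein	ID:ENSOCUP00000006931
Oryzias latipes	medaka	Ol	SMO	predicted protein	ID:ENSORLP00000007986
Pan troglodytes	chimpanzee	Pt	SMO	protein	Swiss-Prot:XP_514493
Pongo abelii	sumatra orangutan	Pa	SMO	predicted protein	GenBank:XP_002830111
Rattus norvegicus	rat	Rn	SMO	protein	Swiss-Prot:XP_001079707
Sus scrofa	pig	Ss	SMO	predicted protein	GenBank:XR_04566
Taeniopygia guttata	zebra finch	Tg	SMO	predicted protein	GenBank:XP_002189301
Takifugu rubripes	japanese pufferfish	Tr	SMO	predicted protein	ID:ENSTRUP00000003466
Tarsius syrinchtae	tarsier	Ts	SMO	predicted protein	ID:ENSTSYP00000002870
Tetraodon nigroviridis	green spotted pufferfish	Tn	SMO	predicted protein	ID:ENSTNIP00000001941
Tursiops truncatus	dolphin	Tt	SMO	predicted protein	ID:ENSTTRP00000009415
Xenopus laevis	african clawed frog	Xl	SMO	protein	Swiss-Prot:Q6INQ4
Xenopus tropicalis	western clawed frog	Xt	SMO	protein	Swiss-Prot:Q28C17
Anolis carolinensis	green anole	An	APAO	predicted protein	XP_003225445
Bos taurus	cattle	Bt	APAO	protein	Swiss-Prot:Q865R1
Callithrix jacchus	pygmy marmoset	Cj	APAO	predicted protein	ID:ENSCJAP00000009627
Cavia porcellus	guinea pig	Cp	APAO	predicted protein	ID:ENSCPOP00000010900
Danio rerio	zebrafish	Dr	APAO	predicted protein	GenBank:XP_690593
Equus caballus	horse	Eq	APAO	predicted protein	ID:ENSECAP00000000093
Gallus gallus	chicken	Gg	APAO	predicted protein	ID:ENSGALP00000005619
Gasterosteus aculeatus	three-spined stickleback	Ga	APAO	predicted protein	GenBank:BT027282
Gorilla gorilla	gorilla	Go	APAO	predicted protein	ID:ENSGGOP00000004628
Homo sapiens	human	Hs	APAO	protein	Swiss-Prot:Q6QHF9-1
Loxodonta africana	elephant	La	APAO	predicted protein	ID:ENSLAFP00000007186
Macaca mulatta	macaque monkey	Ml	APAO	predicted protein	ID:ENSMMUP00000008331
Macropus eugenii	wallaby	Me	APAO	predicted protein	ID:ENSMEUP00000004459
Monodelphis domestica	short-tailed opossum	Md	APAO	predicted protein	ID:ENSMODP00000013113
Mus musculus	house mouse	Mm	APAO	protein	Swiss-Prot:Q4GX45
Oryzias latipes	medaka	Ol	APAO	predicted protein	ID:ENSORLP00000011447
Pongo pygmaeus	orangutan	Pp	APAO	predicted protein	ID:ENSPPYP00000003262
Procavia capensis	hyrax	Pc	APAO	predicted protein	ID:ENSPCAP00000005028
Pteropus vampyrus	megabat	Pv	APAO	predicted protein	ID:ENSPVAG00000002682
Rattus norvegicus	rat	Rn	APAO	protein	Swiss-Prot:Q7TPJ4
Taeniopygia guttata	zebra finch	Tg	APAO	predicted protein	GenBank:XP_002186801
Takifugu rubripes	japanese pufferfish	Tr	APAO	predicted protein	ID:ENSTRUP00000035024
Tetraodon nigroviridis	green spotted pufferfish 1	Tn1	APAO	predicted protein	ID:ENSTNIP00000019636
Tetraodon nigroviridis	green spotted pufferfish 2	Tn2	APAO	predicted protein	ID:ENSTNIP00000002385
Tursiops truncatus	dolphin	Tt	APAO	predicted protein	ID:ENSTTRP00000014996
Xenopus laevis	african clawed frog	Xl	APAO	protein	Swiss-Prot:Q5U4L6
Anopheles gambia	malaria mosquito	Ag	PAO	predicted protein	XP_312316.3
Apis mellifera	honey bee	Am	PAO	predicted protein	GenBank:XP_001122522
Branchiostoma floridae	amphioxus florida lancelet 1	Bf1	PAO	predicted protein	GenBank:XP_002225568
Branchiostoma floridae	amphioxus florida lancelet 2	Bf2	PAO	predicted protein	GenBank:XP_002606976
Caenorhabditis elegans	nematode roundworm	Ce	PAO	predicted protein	GenBank:NP_001023872
Ciona intestinalis	sea squirt	Ci	PAO	predicted protein	XP_002132119
Drosophila melanogaster	fruit fly	Dm	PAO	protein	Swiss-Prot:Q9VHN8
Nasonia vitripennis	jewel wasp	Nv	PAO	predicted protein	XP_001599761
Nematostella vectensis	starlet sea anemone	Ne	PAO	predicted protein	GenBank:XP_001626025
Pediculus humanus corporis	human body louse	Ph	PAO	predicted protein	GenBank:EEB13427
Saccharomyces cerevisiae	baker's yeast	Sc	PAO	protein	GenBank:YDL174C
Strongylocentrotus purpuratus	purple urchin	Sp	PAO	predicted protein	GenBank:XP_001195328
Tribolium castaneum	red flour beetle	Tc	PAO	predicted protein	GenBank:XP_971067
Trichoplax adhaerens	tablet animal-Placozoa	Ta	PAO	predicted protein	GenBank:XP_002107802
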