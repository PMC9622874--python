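drug	label	lncrnas
Panobinostat	negative	NEAT1,H19
Diamorphine	negative	NEAT1
Deferasirox	negative	NEAT1
Ubiquinol	negative	NEAT1
Nilotinib	negative	NEAT1,XIST
Rosiglitazone	negative	NEAT1
Trovafloxacin	negative	NEAT1
Sangivamycin	negative	NEAT1,XIST
Bisphenol A	negative	NEAT1
Bexarotene	negative	NEAT1
beta-Asarone	negative	MALAT1
Bleomycin	negative	MALAT1
Oxaliplatin	negative	H19,MALAT1
Vincristine	negative	H19,MALAT1
Etanercept	negative	H19
Doxycycline	negative	H19
Azathioprine	negative	H19
Decitabine	negative	XIST,H19
Etoposide	negative	H19
Verapamil	negative	H19
Epirubicin	negative	H19
Pirarubicin	negative	H19
Bortezomib	negative	H19
Azacitidine	negative	XIST
Adriamycin	positive	NEAT1,MALAT1
Dexamethasone	positive	NEAT1
Arachidonic acid	positive	NEAT1
Sorafenib	positive	NEAT1
Estradiol	positive	NEAT1
Clinafloxacin	positive	NEAT1
Fluorouracil	positive	NEAT1
Oxymatrine	positive	MALAT1
Quercetin	positive	XIST,MALAT1
PMA	positive	MALAT1
Curcumin	positive	H19
PLX4720	positive	H19
MK-886	positive	H19
Tamoxifen	positive	H19
Fulvestrant	positive	H19
Diclofenac	positive	XIST
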