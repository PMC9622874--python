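lncrna	direction_dm	direction_ad
NEAT1	up	up
XIST	up	up
HCG18	up	up
EBLN3P	up	up
H19	up	up
MALAT1	down	down
PSMA3-AS1	unknown	unknown
AC021078.1	unknown	unknown
AC005261.1	unknown	unknown
AC024940.6	unknown	unknown
NORAD	unknown	unknown
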