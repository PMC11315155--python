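compound,threshold_ug_per_L
Octanoic acid,500.0
Decanoic acid,130.0
Ethanol,10000.0
Phenylethyl alcohol,250.0
Isoamyl alcohol,250.0
2-Nonanol,58.0
1-Nonanol,34.0
Benzaldehyde,350.0
Benzeneacetaldehyde,4.0
3-Methylbutanal,120.0
5-Methyl-2-furaldehyde,16.0
Methacrylaldehyde,25.0
Ethyl acetate,5.0
Ethyl octanoate,5.0
Ethyl decanoate,200.0
Diethyl succinate,1200.0
2-Octyl acetate,38.0
Isoamyl acetate,30.0
Isoamyl lactate,3.0
Ethyl hexanoate,14.0
Ethyl isobutyrate,5.6
Ethyl butyrate,20.0
Ethyl phenylacetate,73.0
Ethyl 2-methylbutyrate,18.0
Ethyl heptanoate,2.0
gamma-Undecalactone,4.0
Ethyl isovalerate,3.0
Ethyl benzoate,500.0
Ethyl valerate,5.0
gamma-Nonalactone,65.0
2-Methylbutyl acetate,11.0
Styrene,100.0
2-(Ethoxymethyl)furan,11.0
"1,1,6-Trimethyl-1,2-dihydronaphthalene",2.5
4-Ethyl-2-methoxyphenol,6.9
4-Ethylphenol,51.0
alpha-Ionone,8.0
Linalool,6.0
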