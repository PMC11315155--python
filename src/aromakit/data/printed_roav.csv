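compound,wine,printed_oav
Octanoic acid,YJ,<1
Octanoic acid,JJ,1.1
Octanoic acid,ZY,<1
Decanoic acid,YJ,<1
Decanoic acid,JJ,<1
Decanoic acid,CC,<1
Decanoic acid,ZY,2.04
Ethanol,YJ,<1
Ethanol,JJ,<1
Ethanol,NEH,<1
Ethanol,GLS,<1
Ethanol,SKM,<1
Ethanol,KJS,1.16
Ethanol,XH,<1
Ethanol,CC,<1
Ethanol,ZY,1.03
Phenylethyl alcohol,YJ,4.91
Phenylethyl alcohol,JJ,10.81
Phenylethyl alcohol,NEH,9.27
Phenylethyl alcohol,GLS,27.14
Phenylethyl alcohol,SKM,27.22
Phenylethyl alcohol,KJS,36.64
Phenylethyl alcohol,XH,24.85
Phenylethyl alcohol,CC,17.62
Phenylethyl alcohol,ZY,39.93
Isoamyl alcohol,YJ,4.25
Isoamyl alcohol,JJ,3.12
Isoamyl alcohol,NEH,2.9
Isoamyl alcohol,GLS,3.29
Isoamyl alcohol,SKM,2.8
Isoamyl alcohol,KJS,5.96
Isoamyl alcohol,XH,4.84
Isoamyl alcohol,CC,6.95
Isoamyl alcohol,ZY,12.83
2-Nonanol,YJ,<1
2-Nonanol,JJ,1.41
2-Nonanol,XH,<1
2-Nonanol,ZY,<1
1-Nonanol,CC,<1
1-Nonanol,ZY,1.74
Benzaldehyde,YJ,<1
Benzaldehyde,JJ,<1
Benzaldehyde,NEH,<1
Benzaldehyde,GLS,16.45
Benzaldehyde,SKM,10.93
Benzaldehyde,KJS,11.07
Benzaldehyde,XH,<1
Benzeneacetaldehyde,YJ,<1
Benzeneacetaldehyde,JJ,12.63
Benzeneacetaldehyde,NEH,48.03
Benzeneacetaldehyde,KJS,11.68
Benzeneacetaldehyde,XH,14.33
3-Methylbutanal,NEH,2.48
5-Methyl-2-furaldehyde,NEH,2.52
Methacrylaldehyde,GLS,7.77
Methacrylaldehyde,SKM,8.24
Methacrylaldehyde,KJS,5.64
Ethyl acetate,YJ,281.4
Ethyl acetate,JJ,338.91
Ethyl acetate,NEH,378.78
Ethyl acetate,GLS,357.32
Ethyl acetate,SKM,176.6
Ethyl acetate,KJS,354.08
Ethyl acetate,XH,373.77
Ethyl acetate,CC,938.28
Ethyl acetate,ZY,253.05
Ethyl octanoate,YJ,231.97
Ethyl octanoate,JJ,344.08
Ethyl octanoate,NEH,66.53
Ethyl octanoate,GLS,54.15
Ethyl octanoate,SKM,36.2
Ethyl octanoate,KJS,63.37
Ethyl octanoate,XH,238.43
Ethyl octanoate,CC,556.96
Ethyl octanoate,ZY,255.22
Ethyl decanoate,YJ,2.28
Ethyl decanoate,JJ,2.02
Ethyl decanoate,NEH,1.39
Ethyl decanoate,SKM,<1
Ethyl decanoate,KJS,<1
Ethyl decanoate,XH,<1
Ethyl decanoate,CC,5.22
Ethyl decanoate,ZY,1.81
Diethyl succinate,YJ,<1
Diethyl succinate,JJ,<1
Diethyl succinate,NEH,<1
Diethyl succinate,GLS,1.23
Diethyl succinate,SKM,<1
Diethyl succinate,KJS,2.74
Diethyl succinate,XH,1.52
Diethyl succinate,CC,2.13
Diethyl succinate,ZY,4.39
2-Octyl acetate,YJ,2.17
2-Octyl acetate,JJ,2.89
2-Octyl acetate,NEH,3.03
2-Octyl acetate,GLS,4.32
2-Octyl acetate,SKM,3.2
2-Octyl acetate,KJS,4.27
2-Octyl acetate,XH,4.68
2-Octyl acetate,CC,1.6
2-Octyl acetate,ZY,<1
Isoamyl acetate,YJ,2.39
Isoamyl acetate,JJ,4.88
Isoamyl acetate,NEH,2.78
Isoamyl acetate,GLS,1.16
Isoamyl acetate,SKM,<1
Isoamyl acetate,KJS,<1
Isoamyl acetate,XH,3.64
Isoamyl acetate,CC,3.14
Isoamyl acetate,ZY,3.03
Isoamyl lactate,YJ,11.98
Isoamyl lactate,JJ,133.47
Isoamyl lactate,GLS,10.74
Isoamyl lactate,SKM,5.65
Isoamyl lactate,KJS,21.85
Isoamyl lactate,XH,16.92
Isoamyl lactate,CC,5.39
Isoamyl lactate,ZY,28.97
Ethyl hexanoate,YJ,2.18
Ethyl isobutyrate,YJ,4.138
Ethyl isobutyrate,JJ,3.914
Ethyl isobutyrate,NEH,16.379
Ethyl isobutyrate,XH,2.82
Ethyl isobutyrate,CC,10.168
Ethyl butyrate,YJ,<1
Ethyl butyrate,JJ,1.82
Ethyl butyrate,NEH,1.07
Ethyl butyrate,GLS,1.38
Ethyl butyrate,KJS,<1
Ethyl butyrate,XH,1.1
Ethyl butyrate,CC,<1
Ethyl butyrate,ZY,<1
Ethyl phenylacetate,YJ,<1
Ethyl phenylacetate,JJ,<1
Ethyl phenylacetate,NEH,<1
Ethyl phenylacetate,GLS,3.91
Ethyl phenylacetate,SKM,2.45
Ethyl phenylacetate,KJS,4.09
Ethyl phenylacetate,XH,<1
Ethyl phenylacetate,CC,<1
Ethyl phenylacetate,ZY,<1
Ethyl 2-methylbutyrate,YJ,<1
Ethyl 2-methylbutyrate,JJ,1.39
Ethyl 2-methylbutyrate,CC,<1
Ethyl 2-methylbutyrate,ZY,<1
Ethyl heptanoate,YJ,1.22
Ethyl heptanoate,JJ,4.3
Ethyl heptanoate,NEH,1.63
Ethyl heptanoate,GLS,20.91
Ethyl heptanoate,SKM,3.83
Ethyl heptanoate,KJS,20.29
Ethyl heptanoate,XH,4.97
gamma-Undecalactone,YJ,<1
gamma-Undecalactone,JJ,1.45
gamma-Undecalactone,NEH,3.07
gamma-Undecalactone,KJS,15.08
Ethyl isovalerate,JJ,4.29
Ethyl isovalerate,NEH,39.38
Ethyl isovalerate,GLS,14.68
Ethyl isovalerate,SKM,5.23
Ethyl isovalerate,CC,2.07
Ethyl isovalerate,ZY,2.25
Ethyl benzoate,GLS,1.15
Ethyl benzoate,SKM,<1
Ethyl benzoate,KJS,<1
Ethyl valerate,GLS,3.58
Ethyl valerate,KJS,3.53
gamma-Nonalactone,KJS,1.25
2-Methylbutyl acetate,YJ,2.3
Styrene,KJS,1.16
2-(Ethoxymethyl)furan,YJ,1.91
2-(Ethoxymethyl)furan,JJ,9.18
2-(Ethoxymethyl)furan,NEH,1.1
2-(Ethoxymethyl)furan,SKM,1.51
2-(Ethoxymethyl)furan,CC,<1
2-(Ethoxymethyl)furan,ZY,1.59
"1,1,6-Trimethyl-1,2-dihydronaphthalene",CC,9.23
"1,1,6-Trimethyl-1,2-dihydronaphthalene",ZY,8.61
4-Ethyl-2-methoxyphenol,YJ,3.67
4-Ethyl-2-methoxyphenol,JJ,12.48
4-Ethyl-2-methoxyphenol,CC,7.68
4-Ethylphenol,YJ,<1
4-Ethylphenol,JJ,1.75
4-Ethylphenol,NEH,<1
4-Ethylphenol,CC,1.95
4-Ethylphenol,ZY,<1
alpha-Ionone,CC,20.29
alpha-Ionone,ZY,12.68
Linalool,ZY,2.16
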