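chem_class,YJ,JJ,NEH,GLS,SKM,KJS,XH,CC,ZY
acid,933.38,671.03,6.58,31.58,11.02,16.84,21.25,86.97,767.10
alcohol,7844.28,6859.95,5859.07,15105.31,16575.76,22909.24,14689.63,16731.91,24290.54
aldehyde,31.74,592.92,3131.71,7762.23,5709.46,5954.80,1387.48,68.58,110.53
ester,4910.12,8092.48,4228.98,5482.05,3302.94,8379.61,6449.53,12350.18,9516.72
other,205.30,576.55,888.30,494.34,359.82,526.29,451.82,501.40,404.75
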