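compound	threshold
linalool	1.0
beta-ionone	0.5
6-methyl-5-hepten-2-one	2.0
2,5-dimethylpyrazine	5.0
gamma-butyrolactone	20.0
hexanal	4.0
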