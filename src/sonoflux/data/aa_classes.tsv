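amino_acid	taste_class
Glu	umami
Asp	umami
Ala	sweet
Thr	sweet
Ser	sweet
Gly	sweet
Val	bitter
Leu	bitter
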