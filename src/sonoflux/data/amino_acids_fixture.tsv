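amino_acid	PT-G	PT-D	PT-F	PT-R	PT-C	PT-A
Glu	2.803457	2.902447	2.989336	3.06699	3.137334	3.201725
Asp	2.979548	3.078538	3.165427	3.243082	3.313425	3.377816
Ala	3.021189	3.046495	3.070407	3.093071	3.114611	3.135133
Thr	2.875061	2.900367	2.924279	2.946943	2.968483	2.989005
Ser	2.875061	2.900367	2.924279	2.946943	2.968483	2.989005
Gly	2.653213	2.678518	2.702431	2.725095	2.746634	2.767156
Val	2.414973	2.440909	2.465383	2.488551	2.510545	2.531479
Leu	2.477121	2.502427	2.526339	2.549003	2.570543	2.591065
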