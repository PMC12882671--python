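sample	GA	EGC	C	CAF	EC	EGCG	ECG
PT-G	17818.1818	21777.7778	3500.0	32000.0	6000.0	40404.0404	18000.0
PT-D	22339.8143	27304.2175	3430.0	32000.0	5280.0	30355.9682	15120.0
PT-F	26346.2024	32200.914	3360.0	32000.0	4560.0	21452.8836	12240.0
PT-R	29518.475	36078.1361	3290.0	32000.0	3840.0	14403.389	9360.0
PT-C	31813.9535	38883.7209	3220.0	32000.0	3120.0	9302.3256	6480.0
PT-A	30193.5484	36903.2258	3150.0	32000.0	2400.0	12903.2258	3600.0
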