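power	p_input_w	time_s	temperature_c
0.3	30.0	0.0	25.0
0.3	30.0	2.0	25.087434
0.3	30.0	4.0	25.174869
0.3	30.0	6.0	25.262303
0.3	30.0	8.0	25.349737
0.3	30.0	10.0	25.437172
0.3	30.0	12.0	25.524606
0.3	30.0	14.0	25.61204
0.3	30.0	16.0	25.699474
0.3	30.0	18.0	25.786909
0.3	30.0	20.0	25.874343
0.3	30.0	22.0	25.961777
0.3	30.0	24.0	26.049212
0.3	30.0	26.0	26.136646
0.3	30.0	28.0	26.22408
0.3	30.0	30.0	26.311515
0.3	30.0	32.0	26.381462
0.3	30.0	34.0	26.451409
0.3	30.0	36.0	26.521357
0.3	30.0	38.0	26.591304
0.3	30.0	40.0	26.661252
0.3	30.0	42.0	26.731199
0.3	30.0	44.0	26.801147
0.3	30.0	46.0	26.871094
0.3	30.0	48.0	26.941042
0.3	30.0	50.0	27.010989
0.3	30.0	52.0	27.080936
0.3	30.0	54.0	27.150884
0.3	30.0	56.0	27.220831
0.3	30.0	58.0	27.290779
0.3	30.0	60.0	27.360726
0.4	40.0	0.0	25.0
0.4	40.0	2.0	25.122695
0.4	40.0	4.0	25.245389
0.4	40.0	6.0	25.368084
0.4	40.0	8.0	25.490779
0.4	40.0	10.0	25.613473
0.4	40.0	12.0	25.736168
0.4	40.0	14.0	25.858863
0.4	40.0	16.0	25.981558
0.4	40.0	18.0	26.104252
0.4	40.0	20.0	26.226947
0.4	40.0	22.0	26.349642
0.4	40.0	24.0	26.472336
0.4	40.0	26.0	26.595031
0.4	40.0	28.0	26.717726
0.4	40.0	30.0	26.84042
0.4	40.0	32.0	26.938576
0.4	40.0	34.0	27.036732
0.4	40.0	36.0	27.134888
0.4	40.0	38.0	27.233043
0.4	40.0	40.0	27.331199
0.4	40.0	42.0	27.429355
0.4	40.0	44.0	27.527511
0.4	40.0	46.0	27.625667
0.4	40.0	48.0	27.723822
0.4	40.0	50.0	27.821978
0.4	40.0	52.0	27.920134
0.4	40.0	54.0	28.01829
0.4	40.0	56.0	28.116445
0.4	40.0	58.0	28.214601
0.4	40.0	60.0	28.312757
0.6	60.0	0.0	25.0
0.6	60.0	2.0	25.202389
0.6	60.0	4.0	25.404778
0.6	60.0	6.0	25.607167
0.6	60.0	8.0	25.809556
0.6	60.0	10.0	26.011945
0.6	60.0	12.0	26.214333
0.6	60.0	14.0	26.416722
0.6	60.0	16.0	26.619111
0.6	60.0	18.0	26.8215
0.6	60.0	20.0	27.023889
0.6	60.0	22.0	27.226278
0.6	60.0	24.0	27.428667
0.6	60.0	26.0	27.631056
0.6	60.0	28.0	27.833445
0.6	60.0	30.0	28.035834
0.6	60.0	32.0	28.197745
0.6	60.0	34.0	28.359656
0.6	60.0	36.0	28.521567
0.6	60.0	38.0	28.683478
0.6	60.0	40.0	28.845389
0.6	60.0	42.0	29.007301
0.6	60.0	44.0	29.169212
0.6	60.0	46.0	29.331123
0.6	60.0	48.0	29.493034
0.6	60.0	50.0	29.654945
0.6	60.0	52.0	29.816856
0.6	60.0	54.0	29.978767
0.6	60.0	56.0	30.140678
0.6	60.0	58.0	30.30259
0.6	60.0	60.0	30.464501
0.8	80.0	0.0	25.0
0.8	80.0	2.0	25.294314
0.8	80.0	4.0	25.588629
0.8	80.0	6.0	25.882943
0.8	80.0	8.0	26.177258
0.8	80.0	10.0	26.471572
0.8	80.0	12.0	26.765886
0.8	80.0	14.0	27.060201
0.8	80.0	16.0	27.354515
0.8	80.0	18.0	27.648829
0.8	80.0	20.0	27.943144
0.8	80.0	22.0	28.237458
0.8	80.0	24.0	28.531773
0.8	80.0	26.0	28.826087
0.8	80.0	28.0	29.120401
0.8	80.0	30.0	29.414716
0.8	80.0	32.0	29.650167
0.8	80.0	34.0	29.885619
0.8	80.0	36.0	30.12107
0.8	80.0	38.0	30.356522
0.8	80.0	40.0	30.591973
0.8	80.0	42.0	30.827425
0.8	80.0	44.0	31.062876
0.8	80.0	46.0	31.298328
0.8	80.0	48.0	31.533779
0.8	80.0	50.0	31.769231
0.8	80.0	52.0	32.004682
0.8	80.0	54.0	32.240134
0.8	80.0	56.0	32.475585
0.8	80.0	58.0	32.711037
0.8	80.0	60.0	32.946488
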