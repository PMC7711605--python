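source	target	standardized_weight	p_value
Group4	Group2	0.353	***
Group4	Group7	-0.285	***
Group4	Group6	0.472	***
Group2	Group6	0.249	***
Group2	Group8	-0.383	***
Group7	Group8	0.178	0.004
Group6	Group9	0.364	***
Group2	Group9	-0.177	0.009
Group7	Group9	0.362	***
Group6	Group1	0.549	***
Group2	Group5	0.557	***
Group7	Group5	0.304	***
Group4	Group5	0.24	***
Group9	Group1	0.157	0.006
Group2	Group3	0.462	***
Group8	Group1	0.233	***
Group9	Group3	0.476	***
Group8	Group5	0.215	***
Group8	Group3	-0.152	0.001
Group6	Group3	0.241	***
Group4	Group3	-0.189	***
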