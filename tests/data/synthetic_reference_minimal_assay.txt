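Sample Name	Protocol REF	Raw Data File
sample_0	data collection	file_0.txt
sample_1	data collection	file_1.txt
sample_2	data collection	file_2.txt
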