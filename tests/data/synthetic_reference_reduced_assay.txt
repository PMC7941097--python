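Sample Name	Protocol REF	Extract Name	Protocol REF	Raw Data File
sample_0	extraction	extract_0	data collection	file_0.txt
sample_1	extraction	extract_1	data collection	file_1.txt
sample_2	extraction	extract_2	data collection	file_2.txt
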