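Source Name	Protocol REF	Sample Name
source_0	sample collection	sample_0
source_1	sample collection	sample_1
source_2	sample collection	sample_2
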