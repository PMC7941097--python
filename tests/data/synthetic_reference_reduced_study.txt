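Source Name	Protocol REF	Sample Name	Characteristics[Organism]	Term Source REF	Term Accession Number
source_0	sample collection	sample_0	Hordeum vulgare	NCBITAXON	http://purl.obolibrary.org/obo/NCBITaxon_4513
source_1	sample collection	sample_1	Hordeum vulgare	NCBITAXON	http://purl.obolibrary.org/obo/NCBITaxon_4513
source_2	sample collection	sample_2	Hordeum vulgare	NCBITAXON	http://purl.obolibrary.org/obo/NCBITaxon_4513
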