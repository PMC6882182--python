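# Example offline annotation table. Key is contig:pos:ref:alt (normalized).
# Fields: gene, consequence, population_frequency, links (db=id;db=id); '.' = absent.
key	gene	consequence	population_frequency	links
7:141672604:T:C	TAS2R38	missense	0.45	dbsnp=rs10246939;clinvar=VCV000447827
7:141673345:G:C	TAS2R38	missense	0.42	dbsnp=rs713598
12:21331549:T:C	SLCO1B1	missense	0.13	dbsnp=rs4149056
19:45411941:T:C	APOE	missense	0.14	dbsnp=rs429358
19:45412079:C:T	APOE	missense	0.08	dbsnp=rs7412
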