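# key	curie	uri	label
apical	FMA:apical_plasma_membrane	https://example.org/fixture/fma#apical_plasma_membrane	apical plasma membrane
basolateral	FMA:basolateral_plasma_membrane	https://example.org/fixture/fma#basolateral_plasma_membrane	basolateral plasma membrane
concentration	OPB:concentration	https://example.org/fixture/opb#concentration	concentration
cytosol	FMA:epithelial_cytosol	https://example.org/fixture/fma#epithelial_cytosol	epithelial cell cytosol
flux	OPB:flux	https://example.org/fixture/opb#flux	flux
glucose	CHEBI:glucose	https://example.org/fixture/chebi#glucose	glucose
hydrogen	CHEBI:hydrogen	https://example.org/fixture/chebi#hydrogen	hydrogen
interstitium	FMA:interstitium	https://example.org/fixture/fma#interstitium	interstitial fluid
membrane	FMA:apical_plasma_membrane	https://example.org/fixture/fma#apical_plasma_membrane	apical plasma membrane
membrane	FMA:basolateral_plasma_membrane	https://example.org/fixture/fma#basolateral_plasma_membrane	basolateral plasma membrane
proximal tubule	FMA:lumen_of_proximal_tubule	https://example.org/fixture/fma#lumen_of_proximal_tubule	proximal tubule
sodium	CHEBI:sodium	https://example.org/fixture/chebi#sodium	sodium
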