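https://example.org/fixture/chebi#glucose	glucose
https://example.org/fixture/chebi#hydrogen	hydrogen
https://example.org/fixture/chebi#sodium	sodium
https://example.org/fixture/fma#apical_plasma_membrane	apical plasma membrane
https://example.org/fixture/fma#basolateral_plasma_membrane	basolateral plasma membrane
https://example.org/fixture/fma#epithelial_cytosol	epithelial cell cytosol
https://example.org/fixture/fma#interstitium	interstitial fluid
https://example.org/fixture/fma#lumen_of_proximal_tubule	proximal tubule
https://example.org/fixture/opb#concentration	concentration
https://example.org/fixture/opb#flux	flux
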