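# prefix	uri-stem
OPB	https://example.org/fixture/opb#
CHEBI	https://example.org/fixture/chebi#
FMA	https://example.org/fixture/fma#
PR	https://example.org/fixture/pr#
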