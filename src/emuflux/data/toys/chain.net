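# Linear chain with a decarboxylation: glucose -> hexose-P -> pentose-P + CO2.
SOURCE GLC 6
SINK R5P
SINK CO2
HK: 1 GLC (abcdef) -> 1 G6P (abcdef)
PPP: 1 G6P (abcdef) -> 1 R5P (bcdef) + 1 CO2 (a)
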