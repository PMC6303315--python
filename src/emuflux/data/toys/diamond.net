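# Diamond: two routes from A to D, one of which reverses the carbon order.
SOURCE A 4
SINK D
R1: 1 A (abcd) -> 1 B (abcd)
R2: 1 A (abcd) -> 1 C (dcba)
R3: 1 B (abcd) -> 1 D (abcd)
R4: 1 C (abcd) -> 1 D (abcd)
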