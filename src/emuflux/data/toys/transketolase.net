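# Transketolase-like carbon exchange: two substrates, two products; the
# seven-carbon product combines atoms from both substrates (convolution).
SOURCE X5P 5
SOURCE R5P 5
SINK SINK7
SINK SINK3
TK: 1 X5P (abcde) + 1 R5P (fghij) -> 1 S7P (abfghij) + 1 GAP (cde)
S1: 1 S7P (abcdefg) -> 1 SINK7 (abcdefg)
G1: 1 GAP (abc) -> 1 SINK3 (abc)
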