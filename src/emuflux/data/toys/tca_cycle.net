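# TCA-like cycle: a condensation (convolution node), CO2 release, and a
# symmetric four-carbon intermediate written as two half-weight variants.
SOURCE PYR 3
SOURCE CO2 1
SINK ASP
PDH: 1 PYR (abc) -> 1 ACCOA (bc) + 1 CO2 (a)
PC: 1 PYR (abc) + 1 CO2 (d) -> 1 OAA (abcd)
CS: 1 ACCOA (ab) + 1 OAA (cdef) -> 1 AKG (defba) + 1 CO2 (c)
TCA2: 1 AKG (abcde) -> 1 OAA (bcde) + 1 CO2 (a)
TCA2: 1 AKG (abcde) -> 1 OAA (edcb) + 1 CO2 (a)
OUT: 1 OAA (abcd) -> 1 ASP (abcd)
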