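# Two-input serine pool (de novo + unlabeled uptake) feeding the
# serine -> glycine + one-carbon cleavage.
SOURCE 3PG 3
SOURCE SER_E 3
SINK GLY
SINK MEETHF
SSP: 1 3PG (abc) -> 1 SER (abc)
SER_UPT: 1 SER_E (abc) -> 1 SER (abc)
SHMT: 1 SER (abc) -> 1 GLY (ab) + 1 MEETHF (c)
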