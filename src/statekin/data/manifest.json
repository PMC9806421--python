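{
 "subunit_expression.csv": "3dd69a09b5d5819c872f500b4a25b75c9188df559cac98a61cc9fa355dba89ee",
 "state_fractions.csv": "9a2b4f9284876d2f3c53de114626ec85f460ce8924ae509bc04a1a8327bbbab5",
 "default_model.json": "294e6b98700e50f3a3ed03080fb12221b8b1200b1b51cb294deb52b413b3f18c"
}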