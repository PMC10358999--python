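# FoldX PositionScan-style single-mutant ddG (kcal/mol)
GA124W -0.996959
GA137W -0.984701
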