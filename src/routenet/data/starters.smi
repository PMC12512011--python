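CC(N)C(=O)O	alanine
C=C	ethene
CCO	ethanol
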