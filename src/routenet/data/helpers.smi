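O	water
O=O	oxygen
[H][H]	hydrogen
[C-]#[O]	carbon monoxide
Cl	hydrogen chloride
ClCl	chlorine
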