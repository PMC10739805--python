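# Core SMAD3-KLF4-PPARG circuit governing epithelial/mesenchymal state dynamics
# in bladder cancer cells. "->" activation, "-|" inhibition.
[nodes]
SMAD3
KLF4
PPARG

[edges]
SMAD3 -> SMAD3
KLF4 -> KLF4
PPARG -> PPARG
SMAD3 -> KLF4
KLF4 -> SMAD3
PPARG -> KLF4
SMAD3 -| PPARG
PPARG -| SMAD3
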