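# Demo lymphoid gene panel (subset of genes recurrently mutated in
# B-cell lymphoma); the production panel is supplied as configuration.
KMT2D
PIM1
SOCS1
BCL2
BCL6
MYD88
CD79B
CD58
CREBBP
EZH2
TNFRSF14
B2M
TP53
CARD11
MYC
IRF4
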