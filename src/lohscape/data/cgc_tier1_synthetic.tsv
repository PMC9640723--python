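gene	tier1_oncogene	oncogenic_effects
AKT1	1	missense
KRAS	1	missense
PIK3CA	1	missense
BRAF	1	missense
TP53	0
NF1	0
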