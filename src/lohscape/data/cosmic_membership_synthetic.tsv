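gene	chromosome	position	ref	alt
AKT1	chr14	105246551	C	T
KRAS	chr12	25398284	C	T
PIK3CA	chr3	178952085	A	G
BRAF	chr7	140453136	A	T
TP53	chr17	7577120	C	T
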