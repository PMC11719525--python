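ExonClass	Total	ASE	SSE	Other	Constitutive
Type1	5651	3095	308	1537	711
Type2	6610	1247	732	2129	2502
Type3	127144	16129	4036	27852	79127
Type4	1556	571	138	536	311
Type5	172	58	7	72	35
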