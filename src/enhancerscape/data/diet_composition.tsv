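item	L	M	H
DE_MJ_per_kg	12.58	12.61	12.65
crude_protein_pct	13.78	13.82	13.86
ash_pct	4.65	4.64	4.62
ether_extract_pct	3.91	4.95	4.01
starch_pct	16.28	23.46	28.35
neutral_detergent_fiber_pct	45.14	36.26	26.33
acid_detergent_fiber_pct	29.17	22.68	16.15
non_fiber_carbohydrates_pct	32.05	42.06	47.92
ca_pct	1.13	1.12	1.12
p_pct	0.24	0.24	0.23
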