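sample	raw_reads	clean_reads	q20	q30	gc
L1	47.000098	46.678932	98.41	95.09	53.55
L2	51.005824	50.628714	98.38	95.11	55.09
L3	45.007044	44.656494	98.41	95.18	55.7
M1	43.924580	43.595780	97.73	93.49	54.1
M2	53.308038	52.883246	97.63	93.26	55.07
M3	53.858538	53.441162	97.41	92.7	53.04
H1	50.221886	49.815570	98.36	95.01	54.37
H2	42.773990	42.465834	97.9	93.88	53.47
H3	42.907606	42.597460	97.7	93.4	53.78
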