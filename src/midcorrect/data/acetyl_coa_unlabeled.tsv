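8.45E+07	1.48E+07	7.38E+05	2.35E+04	0.00E+00	0.00E+00
8.47E+07	1.45E+07	8.45E+05	2.16E+04	0.00E+00	0.00E+00
8.41E+07	1.49E+07	9.58E+05	3.09E+04	0.00E+00	0.00E+00
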