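8.20E+05	1.73E+05	6.91E+03	0.00E+00	0.00E+00	0.00E+00	0.00E+00
8.21E+05	1.70E+05	8.95E+03	0.00E+00	0.00E+00	0.00E+00	0.00E+00
8.09E+05	1.80E+05	1.12E+04	3.18E+02	2.17E+02	0.00E+00	0.00E+00
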