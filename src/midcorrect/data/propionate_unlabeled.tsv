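5.93E+06	1.35E+06	1.88E+06	3.93E+05	1.08E+05	1.67E+04	0.00E+00
7.14E+06	1.63E+06	2.33E+06	4.53E+05	1.63E+05	2.35E+04	2.79E+03
5.85E+06	1.48E+06	2.21E+06	4.56E+05	1.32E+05	2.08E+04	2.97E+03
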