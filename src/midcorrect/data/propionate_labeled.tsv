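9.53E+05	9.56E+05	1.32E+06	5.26E+05	4.00E+05	1.07E+05	9.16E+04
7.04E+05	5.95E+05	8.92E+05	4.45E+05	3.49E+05	7.31E+04	3.22E+04
8.24E+05	7.53E+05	1.15E+06	5.67E+05	4.18E+05	8.31E+04	2.57E+04
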