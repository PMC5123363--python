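5.05E+05	1.04E+05	3.44E+05	7.40E+04	1.24E+05	1.17E+04	1.63E+04
4.97E+05	1.07E+05	3.48E+05	7.79E+04	1.21E+05	5.54E+03	8.94E+03
5.81E+05	1.21E+05	4.11E+05	9.17E+04	1.37E+05	1.37E+04	1.69E+04
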