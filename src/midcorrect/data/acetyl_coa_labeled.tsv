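2.62E+07	4.53E+06	1.28E+07	1.70E+06	0.00E+00	0.00E+00
2.73E+07	4.88E+06	1.38E+07	1.81E+06	0.00E+00	0.00E+00
3.00E+07	5.34E+06	1.47E+07	1.85E+06	0.00E+00	0.00E+00
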