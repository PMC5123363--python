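769011.9	141396.2	12234.4	661.6	25	0.7	0
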