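809264.4	113786.2	36571.6	333.7	42.3	2.7
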