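category	observed	expected_all_survive	expected_wapl_rescues	expected_no_rescue
WaplFloxDel_NipblWT	0	7.25	0	0
WaplDel_NipblWT	19	7.25	11.6	19.333333333333332
WaplFlox_NipblWT	20	7.25	11.6	19.333333333333332
WaplWT_NipblWT	19	7.25	11.6	19.333333333333332
WaplFloxDel_NipblHet	0	7.25	11.6	0
WaplDel_NipblHet	0	7.25	11.6	0
WaplFlox_NipblHet	0	7.25	0	0
WaplWT_NipblHet	0	7.25	0	0
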