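category	observed	expected_all_survive	expected_wapl_rescues	expected_no_rescue
WaplDel_NipblWT	38	19.75	26.333333333333332	39.5
WaplWT_NipblWT	41	19.75	26.333333333333332	39.5
WaplDel_NipblHet	0	19.75	26.333333333333332	0
WaplWT_NipblHet	0	19.75	0	0
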