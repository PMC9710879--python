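category	observed	expected
WaplDelFlox	7	6.5
WaplFloxWT	6	6.5
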