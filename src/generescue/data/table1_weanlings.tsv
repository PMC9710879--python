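category	observed	expected
WaplDelFlox	0	10
WaplFloxWT	20	10
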