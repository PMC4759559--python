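ref_id	group
rbpref_I	I
rbpref_II	II
rbpref_III	III
rbpref_IV	IV
rbpref_V	V
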