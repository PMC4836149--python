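subject_id	label	pair_tag
MCInc_000	MCInc	mixed
MCInc_001	MCInc	mixed
MCIc_000	MCIc	mixed
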