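patient_id	rule	detail
P00050	age	age 19.5 at index
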