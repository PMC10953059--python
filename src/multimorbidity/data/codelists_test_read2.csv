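code,condition_id
451E.,chronic_kidney_disease
451F.,chronic_kidney_disease
451G.,chronic_kidney_disease
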