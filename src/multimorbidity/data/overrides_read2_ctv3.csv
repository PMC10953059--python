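source_code,target_code
E042.,QE042
B011.,QB011
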