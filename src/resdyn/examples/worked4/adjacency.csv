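site_a,site_b,shared_length
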