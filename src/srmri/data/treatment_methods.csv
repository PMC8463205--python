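method,cases
meniscus_suture,17
secondary_resection,39
partial_resection,3
total_resection,1
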