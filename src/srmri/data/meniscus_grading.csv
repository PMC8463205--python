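method,grade_I,grade_II,grade_III
arthroscopy,19,34,7
mri,20,27,13
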