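neutral_mz	labeled_mz	condition
69	70	nitrogen-limited
121	124	nitrogen-limited
143	146	nitrogen-limited
69	70	normal
95	98	normal
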