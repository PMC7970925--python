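nominal_mz	carbons	source
379	1-28	parent ion [M+H-H2O]+, C28H43+ (whole skeleton)
143	1-11	synthetic reconstruction: ring A/B fragment, C11H11+
121	17,20-27	synthetic reconstruction: side chain + C17 less 24-Me, C9H13+
95	20-25,28	synthetic reconstruction: proximal side chain with 24-Me, C7H11+
69	24-28	synthetic reconstruction: side-chain terminus, C5H9+
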