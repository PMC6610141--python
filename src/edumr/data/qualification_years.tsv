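qualification	age_completed_education	pct_of_main_sample
None	15	12.1
CSE/O level/GCSE	16	26.8
NVQ/HND/HNC	18	6.0
A level	18	12.4
Other professional qualification	20	5.1
College or University degree	21	37.5
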