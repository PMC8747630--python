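# Reference mean KTA totals per CDR level used as calibration targets.
# These are the published framework benchmark means for dementia cohorts on a
# kitchen task (see docs/methods.md for provenance and discussion).
cdr0.5: 1.73
cdr1: 4.6
cdr2: 9.67
cdr3: 13.36
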