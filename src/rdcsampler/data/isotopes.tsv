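label	gamma_over_2pi_MHz_per_T
1H	42.577
13C	10.708
15N	-4.316
14N	3.077
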