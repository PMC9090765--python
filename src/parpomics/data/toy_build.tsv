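chromosome	length	centromere_start	centromere_end	acrocentric
1	200000000	90000000	100000000	0
2	200000000	90000000	100000000	0
3	200000000	90000000	100000000	1
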