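# Synthetic example exclusion list (telomeric/centromeric/immunoglobulin-like
# regions). Coordinates match this package's toy four-chromosome genome, not
# any real assembly; replace with your own BED for real data.
1	0	50000	telomere_p
1	2200000	2350000	centromere
1	4450000	4600000	telomere_q
2	0	50000	telomere_p
2	2200000	2350000	centromere
3	0	50000	telomere_p
3	2200000	2350000	centromere
4	0	50000	telomere_p
4	1500000	1600000	igh_like
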