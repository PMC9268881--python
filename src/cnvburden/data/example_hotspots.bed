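# Synthetic example of a recurrent-hotspot BED (name in column 4). These are
# illustrative toy coordinates on the package's synthetic genome; supply your
# own curated hotspot list (e.g. 15q13.3, 16p13.11, 22q11.2) for real data.
1	1500000	2700000	hs1q
2	1500000	2700000	hs2q
3	1500000	2700000	hs3q
4	1500000	2700000	hs4q
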