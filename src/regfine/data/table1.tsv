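population	cohort	cases	controls
Asian	3AS	2487	7620
HC	Han Chinese	1659	3398
EU	European	4036	6958
JAP	Japanese	1347	4486
TOTAL		9529	22462
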