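demo_plasmid	1000	2000	bla	0	+
demo_plasmid	3000	4500	mPer1	0	-
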