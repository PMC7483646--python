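site	partner	ensemble	persistence
D102	R152	charmm27	67.5
D102	R153	charmm27	81.0
D113	R116	charmm22star	44.3
D113	R116	charmm27	55.8
D138	K140	charmm22star	99.8
D138	K140	charmm27	99.8
R152	D102	charmm27	67.5
E246	R245	charmm22star	22.7
D268	K201	charmm22star	98.8
D268	K201	charmm27	93.0
D279	R116	charmm22star	63.2
D279	R116	charmm27	59.4
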