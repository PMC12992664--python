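label	x	y	z
NTO	10.0	5.0	0.0
NPO	30.0	5.0	0.0
NPC1	10.0	25.0	0.0
NPC2	30.0	25.0	0.0
NPC3	10.0	45.0	0.0
NF	30.0	45.0	0.0
NaT	50.0	15.0	0.0
NaF	50.0	35.0	0.0
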