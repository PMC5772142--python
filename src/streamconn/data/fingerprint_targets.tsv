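label	region	x	y	z
BA45	Brodmann area 45	54	24	16
BA2	Brodmann area 2	42	-30	48
OP	Parietal operculum	54	-18	18
BA5	Brodmann area 5	18	-52	62
BA7a	Brodmann area 7 (anterior)	32	-43	58
V1	Primary visual cortex	8	-90	2
FFG	Fusiform gyrus	42	-50	-8
IT	Inferior temporal lobe	35	-36	-20
MTS	Medial temporal sulcus	58	-36	-4
STS	Superior temporal sulcus	58	-28	14
Ins	Insula	52	4	-14
Hipp	Hippocampus	20	-34	-4
OFC	Orbito-frontal cortex	4	58	-14
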