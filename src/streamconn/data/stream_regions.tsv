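area_name	description	stream
TE1a	Area TE1 anterior	ventral
TE1p	Area TE1 posterior	ventral
TE2a	Area TE2 anterior	ventral
TF	Area TF	ventral
TE2p	Area TE2 posterior	ventral
PHT	Area PHT	ventral
PH	Area PH	ventral
TGv	Area TG ventral	ventral
TE1m	Area TE1 middle	ventral
IPS1	Intraparietal sulcus area 1	dorsal
7AL	Lateral area 7A	dorsal
7PI	Lateral area 7P	dorsal
7PC	Area 7PC	dorsal
LIPv	Area lateral intraparietal ventral	dorsal
VIP	Ventral intraparietal complex	dorsal
MIP	Medial intraparietal complex	dorsal
PFt	Area PFt	dorsal
IP2	Area intraparietal 2	dorsal
IP1	Area intraparietal 1	dorsal
PF	Area PF complex	dorsal
PFm	Area PFm complex	dorsal
V6A	Area V6A	dorsal
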