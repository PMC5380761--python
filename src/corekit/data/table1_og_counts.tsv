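sg	n_md_og	n_og_c
SG_I	3	1
SG_II	5	1
SG_III	24	3
SG_IV	1	1
SG_V	4	0
SG_VI	5	0
SG_VIIa	3	0
SG_VIIb	2	0
SG_VIII-1	3	3
SG_VIII-2	3	3
SG_IX	3	1
SG_Xa	2	0
SG_Xb	7	0
SG_XI	22	9
SG_XIIa	6	2
SG_XIIb	1	0
SG_XIIIa	2	0
SG_XIIIb	2	0
SG_XIV	0	0
SG_XV	3	0
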