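name	dnac_position	ciat899_control	ciat899_mannitol	nodd2_control	nodd2_mannitol	also_salt
III (C16:0)		0	1	0	0	1
III (C16:0, NMe)		0	1	0	0	1
III (C18:0)		0	1	0	0	0
III (C18:1)		0	1	0	0	1
III (C18:1, NMe)		0	1	0	0	1
III-Hex (C18:1)		0	1	0	0	0
III-Hex (C18:1, NMe)		0	1	0	0	0
IV (C14:0)		0	1	0	0	1
IV (C14:0, NMe)		0	1	0	0	1
IV (C16:0)		0	1	0	0	1
IV (C16:0, NMe)		0	1	0	0	1
IV (C16:1)		0	1	0	0	1
IV (C18:0)		0	1	0	0	1
IV (C18:0, NMe)		0	1	0	0	1
IV (C18:1)		1	1	1	1	1
IV (C18:1, NMe)		0	1	0	0	1
IV (C18:1, NMe, S)		0	1	0	0	1
IV (C20:1)		0	1	0	0	0
IV-Hex (C16:0, NMe)		0	1	0	0	1
IV-Hex (C18:0)		0	1	0	0	0
IV-Hex (C18:0, NMe)		0	1	0	0	0
IV-Hex (C18:1)		0	1	1	1	1
V (C16:0)		0	1	0	0	1
V (C18:1, NMe) dNAc	3	1	1	0	0	0
V (C18:1, Cb) dNAc	3	0	1	0	0	0
V (C18:1, NMe) dNAc	4	1	1	0	0	0
V (C16:0, NMe)		0	1	0	0	1
V (C18:1)		1	1	1	1	1
V (C18:0)		0	1	0	0	1
V (C18:0, S)		0	1	0	0	0
V (C18:1, NMe)		1	1	1	1	1
V (C18:1, S)		0	1	0	0	1
V (C18:1, NMe, S)		1	1	0	0	1
V (C18:0, NMe, S)		0	1	0	0	1
V (C20:1, NMe)		0	1	0	0	0
V (C20:1, NMe, S)		0	1	0	0	1
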