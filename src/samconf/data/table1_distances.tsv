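# Interproton distances of SAM measured by ROESY at 25 C (H1'-H2' reference, 2.90 +/- 0.2 A)
Atom1	Atom2	Distance_A	Error_A
H3'	H5'	2.10	0.14
H3'	H5''	2.26	0.20
H4'	H5'	2.29	0.16
H4'	H5''	2.46	0.17
Hβ	Hγ'	2.57	0.18
Hα	Hβ	2.70	0.19
H2'	H5''	2.78	0.19
H8	H1'	2.82	0.19
Hγ'	H5''	2.82	0.19
Hβ	Hγ	2.88	0.20
methyl group	Hβ	2.91	0.20
Hγ	H5''	2.99	0.21
Hα	Hγ	2.99	0.21
H1'	H4'	3.02	0.21
methyl group	Hγ'	3.14	0.22
methyl group	H5'	3.14	0.22
Hγ'	H4'	3.16	0.22
Hγ'	H5'	3.22	0.22
methyl group	Hγ	3.23	0.22
H3'	H2	3.23	0.22
Hγ	H5'	3.27	0.23
Hβ	H5''	3.30	0.23
Hγ	H4'	3.50	0.24
H8	H5''	3.52	0.25
H4'	H8	3.54	0.34
methyl group	H4'	3.56	0.25
Hβ	H5'	3.60	0.25
methyl group	H5''	3.61	0.25
methyl group	H3'	3.74	0.27
H2'	H8	3.79	0.26
Hα	Hγ'	3.79	0.26
methyl group	H1'	4.18	0.32
H2	H2'	4.29	0.39
methyl group	Hα	4.32	0.31
Hβ	H2	4.32	0.30
H2	methyl group	5.16	0.38
H2	H1'	5.22	0.50
H8	Hβ	5.34	0.38
H8	H3'	5.82	0.41
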