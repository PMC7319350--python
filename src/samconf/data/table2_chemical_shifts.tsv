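# 1H and 13C chemical shifts of SAM at 25 C. Reference data only; nothing in
# the package computes chemical shifts.
Atom	Multiplet	Shift_1H_ppm	Shift_13C_ppm
2	s	8.27	155.70
8	s	8.30	143.73
1'	d	6.11	91.81
2'	t	4.96	75.16
3'	t	4.60	75.36
4'	mult.	4.57	80.92
5'	d	3.92-3.94	46.87
5''	d	4.03-4.05	46.87
methyl group	s	2.98	26.13
α	t	3.78	55.35
β	quart.	2.34	27.69
γ	t	3.47	41.22
γ'	t	3.68	41.22
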