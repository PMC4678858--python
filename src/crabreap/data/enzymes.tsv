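# crabreap restriction enzyme table (REBASE geometry)
# Cut offsets are between-base indices relative to the recognition start on
# the top strand, top-strand frame: EcoRI G^AATTC, MluCI ^AATT, BbsI GAAGAC(2/6).
# name	recognition	top_cut	bottom_cut
BbsI	GAAGAC	8	12
MluCI	AATT	0	4
EcoRI	GAATTC	1	5
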