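# crabreap monoisotopic mass constants, version 1
# Baseline convention: an oligodeoxyribonucleotide is the neutral molecule;
# summing `residue` rows gives the 5'-phosphate / 3'-OH linear form after
# adding one H2O.  A 5'-OH terminus subtracts HPO3.  `base` rows are the
# neutral nucleobases (BH) used for a-B fragment ions.
# kind	name	formula
residue	A	C10H12N5O5P
residue	C	C9H12N3O6P
residue	G	C10H12N5O6P
residue	T	C10H13N2O7P
base	A	C5H5N5
base	C	C4H5N3O
base	G	C5H5N5O
base	T	C5H6N2O2
group	H2O	H2O
group	HPO3	HPO3
group	AMINOHEXYL	C6H13N
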