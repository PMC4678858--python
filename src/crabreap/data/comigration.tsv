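# crabreap native-PAGE co-migration rules (empirical, declarative)
# Lesion-strand scheme (BbsI first): the 10mer-T and 10mer-C products
# co-migrate; 10mer-A and 10mer-G resolve.  Complementary-strand scheme
# (MluCI first): all four d(AATTATAGCN) species resolve.  The competitor
# 13-mer and putative -1/-2 frameshift products always run apart by length.
# scheme	species	band
bbsi_first	10mer-T	10mer-T/C
bbsi_first	10mer-C	10mer-T/C
bbsi_first	10mer-A	10mer-A
bbsi_first	10mer-G	10mer-G
bbsi_first	13mer	13mer
bbsi_first	10mer	10mer
bbsi_first	9mer	9mer
bbsi_first	8mer	8mer
bbsi_first	long	long
mluci_first	10mer-A	10mer-A
mluci_first	10mer-C	10mer-C
mluci_first	10mer-G	10mer-G
mluci_first	10mer-T	10mer-T
mluci_first	13mer	13mer
mluci_first	10mer	10mer
mluci_first	9mer	9mer
mluci_first	8mer	8mer
mluci_first	long	long
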