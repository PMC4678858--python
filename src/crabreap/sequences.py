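"""Printed assay sequences and the default construct context.

These are the oligonucleotides of the shuttle-vector assay: the 12-mer
lesion ODN (X = O4-alkyldT), the 10-mer it is ligated to, the two scaffolds
that guide ligation of the 22-mer into the EcoRI-linearized single-stranded
M13 genome, the lesion-free competitor 25-mer, and the PCR primers (whose
5' ends carry a hexylamino modifier so that the PCR-product termini cannot
be radiolabeled by polynucleotide kinase).
"""

from __future__ import annotations

from .oligo_core import ODN, AdductSpec

#: 12-mer lesion ODN 5'-ATGGCGXGCTAT-3'; X is the O4-alkyldT lesion.
LESION_12MER = "ATGGCGXGCTAT"

#: Lesion-free counterpart of the 12-mer (X -> T).
CONTROL_12MER = "ATGGCGTGCTAT"

#: 10-mer ligated upstream of the 12-mer to give the 22-mer insert.
UPSTREAM_10MER = "AGTGGAAGAC"

#: Ligation scaffolds spanning the two vector/insert junctions.
SCAFFOLD_1 = "CTTCCACTCACTGAATCATGGTCATAGCTTTC"
SCAFFOLD_2 = "AAAACGACGGCCAGTGAATTATAGC"

#: Lesion-free competitor 25-mer as printed.  Its own vector context (from
#: the earlier competitor-genome construction) is not derivable from the
#: printed sequences; see :data:`SYNTHETIC_COMPETITOR_INSERT`.
COMPETITOR_25MER = "GCAGGATGTCATGGCGATAAGCTAT"

#: SYNTHETIC stand-in insert for the competitor channel: bridges the same
#: two scaffolds as the lesion insert and shares the printed 25-mer's
#: 3'-terminal 15 nt (ATGGCGATAAGCTAT), so both digestion schemes release
#: the competitor's 13-nt fragment.
SYNTHETIC_COMPETITOR_INSERT = "AGTGGAAGACATGGCGATAAGCTAT"

#: PCR primers, 5'-amino modifier stripped.
FWD_PRIMER = "CAGCTATGACCATGATTCAGTGAGTGGA"
REV_PRIMER = "TCGGTGCGGGCCTCTTCGCTATTAC"

#: 0-based lesion position within the 12-mer and the ligated 22-mer.
LESION_SITE_IN_12MER = 6
LESION_SITE_IN_22MER = 16

#: Released product templates: top strand d(GGCGMGCTAT), bottom strand
#: d(AATTATAGCN), with the variable base at TOP_PRODUCT_SITE /
#: BOTTOM_PRODUCT_SITE respectively.
TOP_PRODUCT_TEMPLATE = "GGCG{M}GCTAT"
BOTTOM_PRODUCT_TEMPLATE = "AATTATAGC{N}"
TOP_PRODUCT_SITE = 4
BOTTOM_PRODUCT_SITE = 9

#: SYNTHETIC default vector context downstream of the scaffold-defined
#: flank, a lacZalpha-derived fixture that provides the reverse-primer
#: binding site; it is not the true M13mp7(L2) sequence.  It contains no
#: BbsI/MluCI/EcoRI site.
DEFAULT_DOWNSTREAM_CONTEXT = (
    "ACAACGTCGTGACTGGGAAAACCCTGGCGTTACCCAACTTAATCGCCTTGCAGCACATCC"
    "CCCTTTCGCCAGCTGGCGTAATAGCGAAGAGGCCCGCACCGATCGCC"
)

#: No upstream context is needed: the forward-primer site lies within
#: scaffold reach.
DEFAULT_UPSTREAM_CONTEXT = ""


def lesion_12mer(alkyl_group: str, five_prime: str = "OH") -> ODN:
    """The printed 12-mer carrying the requested O4-alkyldT lesion."""
    return ODN(
        LESION_12MER,
        {LESION_SITE_IN_12MER: AdductSpec(alkyl_group)},
        five_prime=five_prime,
    )


def control_12mer(five_prime: str = "OH") -> ODN:
    return ODN(CONTROL_12MER, five_prime=five_prime)


def upstream_10mer() -> ODN:
    return ODN(UPSTREAM_10MER)
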