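"""Construct assembly, site finding and sequential digestion/labeling."""

import numpy as np
import pytest

from crabreap import sequences as seqs
from crabreap.construct_digest import (
    BBSI_FIRST,
    MLUCI_FIRST,
    AmpliconError,
    AssayScheme,
    AssemblyError,
    DuplexRegion,
    SchemeError,
    assemble_construct,
    default_enzymes,
    enumerate_outcomes,
    extract_amplicon,
    find_sites,
    sequential_digest_label,
)
from crabreap.oligo_core import ODN, ligate
from crabreap.pipeline import build_constructs

from conftest import random_sequence


# ---------------------------------------------------------------------------
# assembly

def test_scaffold_junctions_match_reverse_complement_oracle(constructs):
    from Bio.Seq import Seq

    construct = constructs["control"]
    rc1 = str(Seq(seqs.SCAFFOLD_1).reverse_complement())
    rc2 = str(Seq(seqs.SCAFFOLD_2).reverse_complement())
    up, insert, down = (
        construct.upstream_flank.bases,
        construct.insert.bases,
        construct.downstream_flank.bases,
    )
    # each scaffold's reverse complement spans its junction seamlessly
    assert rc1 in up + insert
    assert (up + insert).index(rc1) + len(rc1) == len(up) + construct.upstream_overlap
    assert rc2 in insert + down
    assert up.endswith("GATTCAGTG")
    assert insert.startswith("AGTGGAAGAC")
    assert insert.endswith("GCTAT")
    assert down.startswith("AATTCACTGGCCGTCGTTTT")


def test_mismatched_scaffold_fails_assembly():
    insert = ODN("AGTGGAAGACATGGCGTGCTAT", five_prime="phosphate")
    bad_scaffold1 = ODN("CTTCCTCTCACTGAATCATGGTCATAGCTTTC")  # one mismatch in arm
    with pytest.raises(AssemblyError, match="junction"):
        assemble_construct(insert, bad_scaffold1, ODN(seqs.SCAFFOLD_2),
                           channel="control")


def test_unphosphorylated_insert_rejected():
    with pytest.raises(AssemblyError, match="phosphorylated"):
        assemble_construct(ODN("AGTGGAAGACATGGCGTGCTAT"), ODN(seqs.SCAFFOLD_1),
                           ODN(seqs.SCAFFOLD_2), channel="control")


def test_control_and_lesion_constructs_share_coordinates(constructs):
    lesion, control = constructs["lesion"], constructs["control"]
    assert lesion.site == control.site
    assert control.insert.lesion_annotations == {}
    assert lesion.insert.lesion_annotations  # X annotated
    assert lesion.site_in_insert == seqs.LESION_SITE_IN_22MER


# ---------------------------------------------------------------------------
# amplicon extraction

def test_amplicon_contains_both_primer_derived_ends(control_duplex):
    assert control_duplex.top.bases.startswith(seqs.FWD_PRIMER)
    from Bio.Seq import Seq

    rc_rev = str(Seq(seqs.REV_PRIMER).reverse_complement())
    assert control_duplex.top.bases.endswith(rc_rev)
    assert control_duplex.top.five_prime == "amino"
    assert control_duplex.bottom.five_prime == "amino"


def test_absent_primer_raises(constructs):
    with pytest.raises(AmpliconError, match="no binding site"):
        extract_amplicon(constructs["control"], fwd_primer="ACGTACGTACGTACGTACGT")


def test_lesion_template_cannot_be_amplified(constructs):
    with pytest.raises(AmpliconError, match="lesion"):
        extract_amplicon(constructs["lesion"])


def test_outcome_duplex_carries_complementary_base(constructs):
    duplexes = {d.outcome: d for d in enumerate_outcomes(constructs["lesion"])}
    d = duplexes["C"]
    n = len(d)
    assert d.top.bases[d.site] == "C"
    assert d.bottom.bases[n - 1 - d.site] == "G"


def test_enumerate_outcomes_yields_four_then_deletions(constructs):
    outs = enumerate_outcomes(constructs["lesion"])
    assert [d.outcome for d in outs] == ["T", "C", "A", "G"]
    with_dels = enumerate_outcomes(constructs["lesion"], include_deletions=True)
    assert [d.outcome for d in with_dels[4:]] == ["del1", "del2"]


def test_control_T_outcome_is_identity(constructs, control_duplex):
    outs = enumerate_outcomes(constructs["control"])
    assert outs[0].outcome == "T"
    assert outs[0].top.bases == control_duplex.top.bases


# ---------------------------------------------------------------------------
# site finding

def test_bbsi_site_geometry_in_insert_context():
    top = ODN("AGTGGAAGACATGGCGTGCTATAATTCACT")
    duplex = DuplexRegion.from_top(top)
    enz = default_enzymes()
    sites = find_sites(duplex, enz["BbsI"])
    assert len(sites) == 1
    # GAAGAC at 4; cut 2 nt after the recognition on top, 6 on bottom
    assert sites[0].top_cut == 4 + 6 + 2
    assert sites[0].bottom_cut == 4 + 6 + 6
    assert sites[0].bottom_cut - sites[0].top_cut == 4  # 4-nt 5' overhang
    mlu = find_sites(duplex, enz["MluCI"])
    assert len(mlu) == 1 and mlu[0].top_cut == top.bases.find("AATT")
    eco = find_sites(DuplexRegion.from_top(ODN("AAAGAATTCTTT")), enz["EcoRI"])
    assert eco[0].top_cut == 4 and eco[0].bottom_cut == 8


def test_find_sites_against_biopython_oracle():
    from Bio.Restriction import BbsI, EcoRI, MluCI
    from Bio.Seq import Seq

    enz = default_enzymes()
    rng = np.random.default_rng(42)
    pairs = {"BbsI": BbsI, "MluCI": MluCI, "EcoRI": EcoRI}
    for _ in range(50):
        seq = random_sequence(rng, 80)
        # plant sites on both strands to exercise the mirror geometry
        seq = seq[:20] + "GAAGAC" + seq[26:50] + "GTCTTC" + seq[56:70] + "AATT"
        duplex = DuplexRegion.from_top(ODN(seq))
        for name, bio_enzyme in pairs.items():
            mine = sorted(s.top_cut for s in find_sites(duplex, enz[name]))
            oracle = sorted(p - 1 for p in bio_enzyme.search(Seq(seq), linear=True))
            assert mine == oracle, f"{name} disagreement on {seq}"


# ---------------------------------------------------------------------------
# sequential digestion with label bookkeeping

def test_bbsi_first_labels_lesion_strand_ten_mer(control_duplex):
    visible = sequential_digest_label(control_duplex, BBSI_FIRST, visible_only=True)
    short = [f for f in visible if len(f) <= 30]
    assert [(f.sequence.bases, f.strand) for f in short] == [("GGCGTGCTAT", "top")]
    assert short[0].sequence.five_prime == "labeled_phosphate"


def test_mluci_first_labels_complementary_strand_ten_mer(control_duplex):
    visible = sequential_digest_label(control_duplex, MLUCI_FIRST, visible_only=True)
    short = [f for f in visible if len(f) <= 30]
    assert [(f.sequence.bases, f.strand) for f in short] == [("AATTATAGCA", "bottom")]


def test_switching_scheme_swaps_labeled_strand_never_both(control_duplex):
    for scheme, strand in ((BBSI_FIRST, "top"), (MLUCI_FIRST, "bottom")):
        visible = sequential_digest_label(control_duplex, scheme, visible_only=True)
        tens = [f for f in visible if len(f) == 10]
        assert len(tens) == 1 and tens[0].strand == strand


def test_label_count_equals_first_digestion_termini(control_duplex):
    # one BbsI site cuts both strands -> exactly two labeled 5' ends
    visible = sequential_digest_label(control_duplex, BBSI_FIRST, visible_only=True)
    assert len(visible) == 2
    assert {f.strand for f in visible} == {"top", "bottom"}


def test_pcr_termini_stay_unlabeled(control_duplex):
    fragments = sequential_digest_label(control_duplex, BBSI_FIRST)
    terminal_top = [f for f in fragments if f.strand == "top" and f.start == 0]
    terminal_bottom = [
        f for f in fragments if f.strand == "bottom" and f.end == len(control_duplex)
    ]
    assert terminal_top[0].sequence.five_prime == "amino"
    assert terminal_bottom[0].sequence.five_prime == "amino"
    assert not terminal_top[0].five_prime_label
    assert not terminal_bottom[0].five_prime_label


def test_large_deletion_mimic_yields_no_labeled_product(control_duplex):
    # remove the BbsI recognition: no 10-mer is released; treated as lack of bypass
    top = control_duplex.top.bases.replace("GGAAGACA", "GGTCGACA")
    duplex = DuplexRegion.from_top(ODN(top, five_prime="amino"), channel="lesion")
    visible = sequential_digest_label(duplex, BBSI_FIRST, visible_only=True)
    assert [f for f in visible if len(f) == 10] == []


def test_competitor_releases_thirteen_mers(competitor_duplex):
    for scheme, expected in (
        (BBSI_FIRST, "GGCGATAAGCTAT"),
        (MLUCI_FIRST, "AATTATAGCTTAT"),
    ):
        visible = sequential_digest_label(competitor_duplex, scheme,
                                          visible_only=True)
        short = [f.sequence.bases for f in visible if len(f) <= 30]
        assert short == [expected]


def test_scheme_missing_step_is_rejected(control_duplex):
    broken = AssayScheme("no_sap", "BbsI", "MluCI", dephosphorylate=False)
    with pytest.raises(SchemeError, match="dephosphorylation"):
        sequential_digest_label(control_duplex, broken)
    with pytest.raises(SchemeError, match="unknown enzyme"):
        sequential_digest_label(
            control_duplex, AssayScheme("bad", "BbsI", "NotAnEnzyme")
        )


def test_fragment_concatenation_conserves_both_strands():
    rng = np.random.default_rng(7)
    enz = default_enzymes()
    for _ in range(100):
        seq = random_sequence(rng, int(rng.integers(40, 120)))
        if rng.random() < 0.7:  # plant sites so cuts actually happen
            i = int(rng.integers(0, len(seq) - 20))
            seq = seq[:i] + "GAAGAC" + seq[i + 6 :]
            j = int(rng.integers(0, len(seq) - 6))
            seq = seq[:j] + "AATT" + seq[j + 4 :]
        duplex = DuplexRegion.from_top(ODN(seq))
        scheme = BBSI_FIRST if rng.random() < 0.5 else MLUCI_FIRST
        fragments = sequential_digest_label(duplex, scheme, enz)
        top = sorted((f for f in fragments if f.strand == "top"),
                     key=lambda f: f.start)
        bottom = sorted((f for f in fragments if f.strand == "bottom"),
                        key=lambda f: -f.start)
        assert "".join(f.sequence.bases for f in top) == duplex.top.bases
        assert "".join(f.sequence.bases for f in bottom) == duplex.bottom.bases


def test_type_iis_overhang_geometry_on_random_substrates():
    rng = np.random.default_rng(11)
    enz = default_enzymes()
    for _ in range(50):
        seq = random_sequence(rng, 60)
        i = int(rng.integers(10, 40))
        seq = seq[:i] + "GAAGAC" + seq[i + 6 :]
        duplex = DuplexRegion.from_top(ODN(seq))
        for site in find_sites(duplex, enz["BbsI"]):
            assert site.bottom_cut - site.top_cut == 4  # 4-nt 5' overhang
        for site in find_sites(duplex, enz["MluCI"]):
            assert site.bottom_cut - site.top_cut == 4  # AATT 5' overhang
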