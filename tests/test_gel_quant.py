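"""Band assignment, bypass-efficiency formula and spectrum solving."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crabreap.construct_digest import LabeledFragment
from crabreap.gel_quant import (
    AssayRun,
    Band,
    BandTable,
    GelError,
    assign_bands,
    band_tables_frame,
    band_tables_from_frame,
    bypass_efficiency,
    detect_frameshifts,
    mutation_spectrum,
    species_of,
)
from crabreap.oligo_core import ODN
from crabreap.synthetic_data import GroundTruth, generate_run


def _fragment(seq, strand="top", channel="lesion", site_base=None, labeled=True):
    return LabeledFragment(
        ODN(seq, five_prime="labeled_phosphate" if labeled else "phosphate"),
        strand, 0, len(seq), labeled, channel, site_base,
    )


# ---------------------------------------------------------------------------
# band assignment / co-migration

def test_ten_mer_T_and_C_comigrate_under_lesion_strand_scheme():
    fragments = [
        _fragment("GGCGTGCTAT", site_base="T"),
        _fragment("GGCGCGCTAT", site_base="C"),
    ]
    table = assign_bands(fragments, "bbsi_first")
    lesion_bands = table.channel_bands("lesion")
    assert len(lesion_bands) == 1
    assert set(lesion_bands[0].species) == {"10mer-T", "10mer-C"}
    assert lesion_bands[0].intensity == 2.0


def test_N_A_and_N_G_resolve_under_complementary_scheme():
    fragments = [
        _fragment("AATTATAGCA", strand="bottom", site_base="A"),
        _fragment("AATTATAGCG", strand="bottom", site_base="G"),
    ]
    table = assign_bands(fragments, "mluci_first")
    assert len(table.channel_bands("lesion")) == 2


def test_competitor_thirteen_mer_always_separate():
    fragments = [
        _fragment("GGCGTGCTAT", site_base="T"),
        _fragment("GGCGATAAGCTAT", channel="competitor"),
    ]
    table = assign_bands(fragments, "bbsi_first")
    assert table.intensity("13mer", "competitor") == 1.0
    assert table.intensity("10mer-T/C", "lesion") == 1.0


def test_unlabeled_fragment_rejected_from_gel():
    with pytest.raises(GelError, match="labeled"):
        assign_bands([_fragment("GGCGTGCTAT", labeled=False)], "bbsi_first")


def test_species_naming():
    assert species_of(_fragment("GGCGAGCTAT", site_base="A")) == "10mer-A"
    assert species_of(_fragment("GGCGATAAGCTAT")) == "13mer"
    assert species_of(_fragment("A" * 80)) == "long"


# ---------------------------------------------------------------------------
# bypass efficiency

def _run(lesion, comp_lesion, control, comp_control, r_lesion=1.0, r_control=1.0,
         replicate=1):
    tables = {}
    for scheme in ("bbsi_first", "mluci_first"):
        tables[(scheme, "lesion")] = BandTable(scheme, [
            Band("10mer-T/C" if scheme == "bbsi_first" else "10mer-A",
                 "lesion", ("10mer-T",), lesion),
            Band("13mer", "competitor", ("13mer",), comp_lesion),
        ])
        tables[(scheme, "control")] = BandTable(scheme, [
            Band("10mer-T/C" if scheme == "bbsi_first" else "10mer-A",
                 "control", ("10mer-T",), control),
            Band("13mer", "competitor", ("13mer",), comp_control),
        ])
    return AssayRun(replicate, r_lesion, r_control, tables)


def test_bypass_formula_worked_example():
    result = bypass_efficiency(_run(40, 20, 80, 20))
    assert result.mean == pytest.approx(50.0)


def test_bypass_identity_lanes_give_hundred_percent():
    result = bypass_efficiency(_run(55, 17, 55, 17))
    assert result.mean == pytest.approx(100.0)


def test_mixing_ratio_correction_halves_at_two_to_one():
    result = bypass_efficiency(_run(40, 20, 80, 20, r_lesion=2.0, r_control=1.0))
    assert result.mean == pytest.approx(25.0)


def test_zero_competitor_is_an_error_not_zero():
    with pytest.raises(GelError, match="competitor"):
        bypass_efficiency(_run(40, 0.0, 80, 20))


@given(st.floats(min_value=0.01, max_value=100.0))
def test_bypass_invariant_under_uniform_lane_rescaling(scale):
    base = bypass_efficiency(_run(40, 20, 80, 20)).mean
    scaled = bypass_efficiency(_run(40 * scale, 20 * scale, 80, 20)).mean
    assert scaled == pytest.approx(base, rel=1e-9)


def test_replicate_aggregation_mean_and_sd():
    runs = [_run(40, 20, 80, 20, replicate=1), _run(60, 20, 80, 20, replicate=2)]
    result = bypass_efficiency(runs)
    assert result.mean == pytest.approx(62.5)
    assert result.sd == pytest.approx(np.std([50.0, 75.0], ddof=1))


# ---------------------------------------------------------------------------
# mutation spectrum

def _spectrum_run(bbsi_bands, mluci_bands, replicate=1):
    tables = {
        ("bbsi_first", "lesion"): BandTable("bbsi_first", [
            Band(b, "lesion", (b.replace("T/C", "T"),), v)
            for b, v in bbsi_bands.items()
        ] + [Band("13mer", "competitor", ("13mer",), 100.0)]),
        ("mluci_first", "lesion"): BandTable("mluci_first", [
            Band(b, "lesion", (b,), v) for b, v in mluci_bands.items()
        ] + [Band("13mer", "competitor", ("13mer",), 100.0)]),
        ("bbsi_first", "control"): BandTable("bbsi_first", [
            Band("10mer-T/C", "control", ("10mer-T",), 100.0),
            Band("13mer", "competitor", ("13mer",), 100.0),
        ]),
        ("mluci_first", "control"): BandTable("mluci_first", [
            Band("10mer-A", "control", ("10mer-A",), 100.0),
            Band("13mer", "competitor", ("13mer",), 100.0),
        ]),
    }
    return AssayRun(replicate, 1.0, 1.0, tables)


def test_direct_proportion_from_complementary_strand():
    run = _spectrum_run(
        {"10mer-T/C": 100.0},
        {"10mer-A": 20.0, "10mer-G": 80.0},
    )
    spec = mutation_spectrum(run).mean
    assert spec.f_C == pytest.approx(0.80, abs=1e-9)
    assert spec.f_T == pytest.approx(0.20, abs=1e-9)
    assert spec.f_A == pytest.approx(0.0, abs=1e-9)
    assert spec.f_G == pytest.approx(0.0, abs=1e-9)
    assert spec.mutation_frequency == pytest.approx(0.80, abs=1e-9)


def test_equal_products_give_quarter_each():
    run = _spectrum_run(
        {"10mer-T/C": 50.0, "10mer-A": 25.0, "10mer-G": 25.0},
        {"10mer-A": 25.0, "10mer-G": 25.0, "10mer-T": 25.0, "10mer-C": 25.0},
    )
    spec = mutation_spectrum(run).mean
    for f in (spec.f_T, spec.f_C, spec.f_A, spec.f_G):
        assert f == pytest.approx(0.25, abs=1e-9)


def test_all_zero_products_is_an_error():
    run = _spectrum_run({"10mer-T/C": 0.0}, {"10mer-A": 0.0})
    with pytest.raises(GelError):
        mutation_spectrum(run)


def test_spectrum_round_trip_with_generator_noise_free():
    truth = (0.15, 0.55, 0.20, 0.10)
    gt = GroundTruth("Me", 0.7, truth, r_lesion=2.0, sigma=0.0, replicates=2)
    runs = generate_run(gt)
    spec = mutation_spectrum(runs).mean
    for observed, expected in zip(
        (spec.f_T, spec.f_C, spec.f_A, spec.f_G), truth
    ):
        assert observed == pytest.approx(expected, abs=1e-9)


def test_tc_split_unaffected_by_lesion_strand_comigration():
    # corrupting the merged T/C band must not move the T vs C split, which
    # the complementary-strand scheme alone determines
    base = _spectrum_run(
        {"10mer-T/C": 100.0},
        {"10mer-A": 30.0, "10mer-G": 70.0},
    )
    skewed = _spectrum_run(
        {"10mer-T/C": 250.0},
        {"10mer-A": 30.0, "10mer-G": 70.0},
    )
    s1, s2 = mutation_spectrum(base).mean, mutation_spectrum(skewed).mean
    assert s1.f_C / (s1.f_T + s1.f_C) == pytest.approx(
        s2.f_C / (s2.f_T + s2.f_C), abs=1e-9
    )


# ---------------------------------------------------------------------------
# frameshifts

def test_frameshift_flagging_and_threshold():
    table = BandTable("bbsi_first", [
        Band("10mer-T/C", "lesion", ("10mer-T",), 95.0),
        Band("9mer", "lesion", ("9mer",), 5.0),
        Band("13mer", "competitor", ("13mer",), 50.0),
    ])
    flags = detect_frameshifts(table, threshold=0.005)
    assert len(flags) == 1
    assert flags[0].kind == "-1"
    assert flags[0].fraction == pytest.approx(0.05)
    assert flags[0].detected

    faint = BandTable("bbsi_first", [
        Band("10mer-T/C", "lesion", ("10mer-T",), 99.9),
        Band("9mer", "lesion", ("9mer",), 0.1),
    ])
    flags = detect_frameshifts(faint, threshold=0.005)
    assert not flags[0].detected

    clean = BandTable("bbsi_first", [
        Band("10mer-T/C", "lesion", ("10mer-T",), 100.0),
        Band("13mer", "competitor", ("13mer",), 50.0),
    ])
    assert detect_frameshifts(clean) == []


def test_frameshift_fractions_enter_the_spectrum():
    gt = GroundTruth("Me", 0.8, (0.4, 0.4, 0.0, 0.0), sigma=0.0, replicates=1,
                     f_del1=0.15, f_del2=0.05)
    spec = mutation_spectrum(generate_run(gt)).mean
    assert spec.f_del1 == pytest.approx(0.15, abs=1e-9)
    assert spec.f_del2 == pytest.approx(0.05, abs=1e-9)
    assert spec.f_T == pytest.approx(0.4, abs=1e-9)


# ---------------------------------------------------------------------------
# TSV round trip

def test_band_table_tsv_round_trip():
    gt = GroundTruth("Et", 0.5, (0.2, 0.8, 0.0, 0.0), sigma=0.1, seed=5)
    runs = generate_run(gt)
    frame = band_tables_frame(runs)
    back = band_tables_from_frame(frame)
    assert bypass_efficiency(back).mean == pytest.approx(
        bypass_efficiency(runs).mean
    )
    assert mutation_spectrum(back).mean.f_C == pytest.approx(
        mutation_spectrum(runs).mean.f_C
    )
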