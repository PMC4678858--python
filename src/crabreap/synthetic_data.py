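"""Ground-truth-parameterized generators standing in for the wet lab.

`generate_run` emulates transfection, in-cell replication, PCR, sequential
digestion/labeling and phosphorimager quantification in one step: expected
band intensities follow the competitive design (competitor ~ 1, lesion
products ~ r_lesion * theta * p_M merged per co-migration rules, control
product ~ r_control), each multiplied by independent lognormal noise
exp(sigma * Z).  `generate_peaklist` emulates the ESI-MS/MS spectra of the
released 10-mers.  Everything is seeded, so a fixed seed fixes every
downstream number end-to-end.

What the generator deliberately does not model: polymerase kinetics, SOS
regulation, repair-protein action, gel background/smearing, and isotope
envelopes.  Those enter only through the scalar parameters theta (bypass
probability) and p (replication-product spectrum).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .gel_quant import AssayRun, Band, BandTable, default_comigration_rules
from .ms_verify import PeakList
from .oligo_core import ALKYL_GROUPS, ODN, fragment_ladder

__all__ = [
    "GroundTruth",
    "generate_run",
    "generate_peaklist",
    "load_scenarios",
    "scenario_ground_truth",
]

#: Arbitrary phosphorimager scale of the competitor band.
BASE_INTENSITY = 1000.0

_SPECIES = ("T", "C", "A", "G")
_M_TO_N = {"T": "A", "C": "G", "A": "T", "G": "C"}


@dataclass(frozen=True)
class GroundTruth:
    """True parameters of one synthetic replication experiment."""

    lesion: str
    bypass: float
    spectrum: tuple[float, float, float, float]  # (f_T, f_C, f_A, f_G)
    r_lesion: float = 2.0
    r_control: float = 1.0
    replicates: int = 3
    sigma: float = 0.1
    seed: int = 0
    f_del1: float = 0.0
    f_del2: float = 0.0

    def __post_init__(self) -> None:
        if self.lesion != "control" and self.lesion not in ALKYL_GROUPS:
            raise ValueError(f"unknown lesion {self.lesion!r}")
        if not (0.0 <= self.bypass <= 1.0):
            raise ValueError("bypass must lie in [0, 1]")
        total = sum(self.spectrum) + self.f_del1 + self.f_del2
        if any(f < 0 for f in self.spectrum) or abs(total - 1.0) > 1e-9:
            raise ValueError("spectrum must lie on the probability simplex")
        if self.replicates < 1:
            raise ValueError("at least one replicate is required")
        if self.sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.r_lesion <= 0 or self.r_control <= 0:
            raise ValueError("mixing ratios must be positive")


def _product_bands(
    scheme: str,
    channel: str,
    weight: float,
    spectrum: Mapping[str, float],
    f_del1: float,
    f_del2: float,
    rules: Mapping[tuple[str, str], str],
) -> dict[tuple[str, str], tuple[set, float]]:
    """Expected (band, channel) -> (species, intensity) for one genome."""
    acc: dict[tuple[str, str], tuple[set, float]] = {}

    def _put(species: str, intensity: float) -> None:
        if intensity <= 0:
            return
        band = rules[(scheme, species)]
        members, total = acc.setdefault((band, channel), (set(), 0.0))
        members.add(species)
        acc[(band, channel)] = (members, total + intensity)

    for m, f in spectrum.items():
        base = m if scheme == "bbsi_first" else _M_TO_N[m]
        _put(f"10mer-{base}", weight * f)
    _put("9mer", weight * f_del1)
    _put("8mer", weight * f_del2)
    return acc


def generate_run(
    gt: GroundTruth,
    rules: Optional[Mapping[tuple[str, str], str]] = None,
) -> list[AssayRun]:
    """Generate one :class:`AssayRun` per replicate (both schemes, both
    lanes), reproducibly from ``gt.seed``."""
    rules = rules if rules is not None else default_comigration_rules()
    rng = np.random.default_rng(gt.seed)
    spectrum = dict(zip(_SPECIES, gt.spectrum))
    runs: list[AssayRun] = []
    for replicate in range(1, gt.replicates + 1):
        tables: dict[tuple[str, str], BandTable] = {}
        for scheme in ("bbsi_first", "mluci_first"):
            for lane, channel_weight, lane_spectrum, d1, d2 in (
                ("lesion", gt.r_lesion * gt.bypass, spectrum, gt.f_del1, gt.f_del2),
                ("control", gt.r_control, {"T": 1.0}, 0.0, 0.0),
            ):
                acc = _product_bands(
                    scheme, lane, BASE_INTENSITY * channel_weight,
                    lane_spectrum, d1, d2, rules,
                )
                comp_band = rules[(scheme, "13mer")]
                members, total = acc.setdefault(
                    (comp_band, "competitor"), (set(), 0.0)
                )
                members.add("13mer")
                acc[(comp_band, "competitor")] = (members, total + BASE_INTENSITY)
                table = BandTable(scheme=scheme)
                for (band_id, channel), (species, expected) in sorted(acc.items()):
                    noise = float(np.exp(gt.sigma * rng.standard_normal()))
                    table.bands.append(
                        Band(band_id, channel, tuple(sorted(species)),
                             expected * noise)
                    )
                tables[(scheme, lane)] = table
        runs.append(
            AssayRun(
                replicate=replicate,
                r_lesion=gt.r_lesion,
                r_control=gt.r_control,
                tables=tables,
            )
        )
    return runs


def generate_peaklist(
    product: ODN,
    charge: int = 3,
    ppm_jitter: float = 0.0,
    seed: int = 0,
    n_decoys: int = 0,
    fragment_charges: Sequence[int] = (1, 2),
    base_intensity: float = 100.0,
) -> PeakList:
    """Synthetic ESI peak list: precursor plus the full w / a-B ladder with
    Gaussian ppm jitter, optionally spiked with uniform decoy peaks."""
    if ppm_jitter < 0:
        raise ValueError("jitter must be non-negative")
    rng = np.random.default_rng(seed)
    ladder = fragment_ladder(product, charges=tuple(fragment_charges),
                             precursor_charge=charge)
    mzs = [ladder.precursor_mz] + ladder.mz_values()
    peaks = []
    for mz in mzs:
        observed = mz * (1.0 + ppm_jitter * 1e-6 * rng.standard_normal())
        peaks.append((observed, base_intensity))
    if n_decoys:
        lo, hi = min(mzs) * 0.9, max(mzs) * 1.1
        for _ in range(n_decoys):
            peaks.append((float(rng.uniform(lo, hi)), base_intensity * 0.2))
    peaks.sort()
    return PeakList(tuple(peaks))


# ---------------------------------------------------------------------------
# Scenario presets

def load_scenarios() -> dict[str, dict]:
    path = resources.files("crabreap").joinpath("data/scenarios.yaml")
    with path.open() as handle:
        return yaml.safe_load(handle)


def scenario_ground_truth(name: str, seed: int = 0,
                          scenarios: Optional[Mapping[str, dict]] = None) -> GroundTruth:
    """Instantiate a preset scenario (one of the eight lesions or
    'control') with the given seed."""
    scenarios = scenarios if scenarios is not None else load_scenarios()
    if name not in scenarios:
        raise KeyError(f"unknown scenario {name!r}")
    params = scenarios[name]
    return GroundTruth(
        lesion=name,
        bypass=float(params["bypass"]),
        spectrum=tuple(float(f) for f in params["spectrum"]),
        r_lesion=float(params["r_lesion"]),
        r_control=float(params["r_control"]),
        replicates=int(params["replicates"]),
        sigma=float(params["sigma"]),
        seed=seed,
    )
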