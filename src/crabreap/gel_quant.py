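"""Gel-band bookkeeping and quantification of bypass and mutation spectra.

A lane contains the labeled products of one genome channel (lesion or
control) co-run with the competitor channel.  Species are named by released
fragment length and, where the fragment covers the replication-product
site, by the base observed there: ``10mer-C`` means d(p*GGCGCGCTAT) under
the lesion-strand scheme and d(p*AATTATAGCC) under the complementary-strand
scheme.  Mobility is empirical and therefore declarative: the shipped
co-migration table merges 10mer-T with 10mer-C under the lesion-strand
(BbsI-first) scheme and resolves all four d(AATTATAGCN) species under the
complementary-strand (MluCI-first) scheme.

Bypass efficiency follows the competitive replication formula

    bypass (%) = (lesion signal / competitor signal)
               / (control signal / competitor signal) x 100

further divided by ``r_lesion / r_control`` to account for the molar
mixing ratios used at transfection.  The mutation spectrum is solved from
both schemes jointly by non-negative least squares on the probability
simplex; the T/C split is informed only by the complementary-strand scheme
(the lesion-strand scheme cannot separate those two products).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .construct_digest import AssayScheme, LabeledFragment

__all__ = [
    "GelError",
    "Band",
    "BandTable",
    "AssayRun",
    "MutationSpectrum",
    "BypassResult",
    "SpectrumResult",
    "FrameshiftFlag",
    "load_comigration_rules",
    "default_comigration_rules",
    "species_of",
    "assign_bands",
    "bypass_efficiency",
    "mutation_spectrum",
    "detect_frameshifts",
    "band_tables_frame",
    "band_tables_from_frame",
]

#: Released product length for substitution outcomes; the competitor
#: fragment runs at 13 nt, putative -1/-2 frameshifts at 9/8 nt.
PRODUCT_LENGTH = 10
COMPETITOR_LENGTH = 13

_SPECIES_LEN_RE = re.compile(r"^(\d+)mer")


class GelError(ValueError):
    """Quantification cannot proceed (missing band, zero competitor, ...)."""


def load_comigration_rules(path: str | Path) -> dict[tuple[str, str], str]:
    rules: dict[tuple[str, str], str] = {}
    with open(path) as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "scheme":
                continue
            rules[(row[0], row[1])] = row[2]
    return rules


def default_comigration_rules() -> dict[tuple[str, str], str]:
    path = resources.files("crabreap").joinpath("data/comigration.tsv")
    with resources.as_file(path) as p:
        return load_comigration_rules(p)


def species_of(fragment: LabeledFragment, max_resolved: int = 30) -> str:
    """Species name of a labeled fragment: length, plus the site base when
    the fragment reports the replication-product position."""
    length = len(fragment)
    if length > max_resolved:
        return "long"
    if fragment.site_base is not None:
        return f"{length}mer-{fragment.site_base}"
    return f"{length}mer"


def species_length(species: str) -> Optional[int]:
    m = _SPECIES_LEN_RE.match(species)
    return int(m.group(1)) if m else None


@dataclass
class Band:
    band_id: str
    channel: str
    species: tuple[str, ...]
    intensity: float

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("band intensity must be non-negative")


@dataclass
class BandTable:
    """Quantified bands of one lane under one digestion scheme."""

    scheme: str
    bands: list[Band] = field(default_factory=list)

    def intensity(self, band_id: str, channel: Optional[str] = None) -> float:
        return sum(
            b.intensity
            for b in self.bands
            if b.band_id == band_id and (channel is None or b.channel == channel)
        )

    def channel_bands(self, channel: str) -> list[Band]:
        return [b for b in self.bands if b.channel == channel]

    def product_signal(self, channel: str, length: int = PRODUCT_LENGTH) -> float:
        """Summed intensity of all bands of the given released-fragment
        length for a channel (all 10-mer bands by default)."""
        total = 0.0
        for b in self.channel_bands(channel):
            lengths = {species_length(s) for s in b.species}
            if lengths == {length}:
                total += b.intensity
        return total


def assign_bands(
    fragments: Iterable[LabeledFragment],
    scheme: AssayScheme | str,
    rules: Optional[Mapping[tuple[str, str], str]] = None,
    weights: Optional[Sequence[float]] = None,
) -> BandTable:
    """Group labeled fragments into gel bands under the co-migration rules.

    Intensities are summed fragment weights (unit weight per fragment by
    default); a fragment whose species has no mobility class raises
    :class:`GelError`.
    """
    scheme_name = scheme.name if isinstance(scheme, AssayScheme) else scheme
    rules = rules if rules is not None else default_comigration_rules()
    fragments = list(fragments)
    if weights is None:
        weights = [1.0] * len(fragments)
    acc: dict[tuple[str, str], tuple[set[str], float]] = {}
    for fragment, w in zip(fragments, weights):
        if not fragment.five_prime_label:
            raise GelError("only labeled fragments appear on the gel")
        sp = species_of(fragment)
        try:
            band_id = rules[(scheme_name, sp)]
        except KeyError:
            raise GelError(
                f"species {sp!r} has no mobility class under scheme "
                f"{scheme_name!r}"
            ) from None
        members, total = acc.setdefault((band_id, fragment.origin_channel),
                                        (set(), 0.0))
        members.add(sp)
        acc[(band_id, fragment.origin_channel)] = (members, total + w)
    table = BandTable(scheme=scheme_name)
    for (band_id, channel), (members, total) in sorted(acc.items()):
        table.bands.append(Band(band_id, channel, tuple(sorted(members)), total))
    return table


@dataclass
class AssayRun:
    """One replicate: both schemes for the lesion+competitor lane and the
    control+competitor lane, plus the transfection mixing ratios."""

    replicate: int
    r_lesion: float
    r_control: float
    tables: dict[tuple[str, str], BandTable]  # (scheme, lane) -> table

    def __post_init__(self) -> None:
        if self.r_lesion <= 0 or self.r_control <= 0:
            raise ValueError("mixing ratios must be positive")

    def table(self, scheme: str, lane: str) -> BandTable:
        try:
            return self.tables[(scheme, lane)]
        except KeyError:
            raise GelError(f"run {self.replicate} lacks ({scheme}, {lane}) table")


@dataclass(frozen=True)
class MutationSpectrum:
    """Simplex-constrained frequencies of the base read at the lesion site."""

    f_T: float
    f_C: float
    f_A: float
    f_G: float
    f_del1: float = 0.0
    f_del2: float = 0.0

    def __post_init__(self) -> None:
        values = (self.f_T, self.f_C, self.f_A, self.f_G, self.f_del1, self.f_del2)
        if any(v < -1e-9 for v in values):
            raise ValueError("frequencies must be non-negative")
        if abs(sum(values) - 1.0) > 1e-6:
            raise ValueError("frequencies must sum to 1")

    @property
    def mutation_frequency(self) -> float:
        """1 minus the frequency of the non-mutagenic (T) outcome."""
        return 1.0 - self.f_T

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.f_T, self.f_C, self.f_A, self.f_G, self.f_del1, self.f_del2]
        )


@dataclass(frozen=True)
class BypassResult:
    mean: float
    sd: float
    per_replicate: tuple[float, ...]


@dataclass(frozen=True)
class SpectrumResult:
    mean: MutationSpectrum
    sd: tuple[float, ...]
    per_replicate: tuple[MutationSpectrum, ...]

    @property
    def mutation_frequency_mean(self) -> float:
        return float(np.mean([s.mutation_frequency for s in self.per_replicate]))

    @property
    def mutation_frequency_sd(self) -> float:
        return _sd([s.mutation_frequency for s in self.per_replicate])


def _sd(values: Sequence[float]) -> float:
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def _as_runs(run: "AssayRun | Sequence[AssayRun]") -> list[AssayRun]:
    return [run] if isinstance(run, AssayRun) else list(run)


def bypass_efficiency(
    run: AssayRun | Sequence[AssayRun],
    scheme: str = "bbsi_first",
    product_length: int = PRODUCT_LENGTH,
) -> BypassResult:
    """Competitor-normalized bypass efficiency in percent, mean +/- SD.

    Per replicate: the lesion signal is the summed intensity of *all*
    product-length bands in the lesion channel; the same quantity in the
    control channel normalizes for transfection/amplification, and the
    competitor band normalizes each lane internally.  The result is further
    divided by ``r_lesion / r_control``.
    """
    values = []
    for r in _as_runs(run):
        lesion_tab = r.table(scheme, "lesion")
        control_tab = r.table(scheme, "control")
        lesion = lesion_tab.product_signal("lesion", product_length)
        control = control_tab.product_signal("control", product_length)
        comp_lesion = lesion_tab.product_signal("competitor", COMPETITOR_LENGTH)
        comp_control = control_tab.product_signal("competitor", COMPETITOR_LENGTH)
        if comp_lesion <= 0 or comp_control <= 0:
            raise GelError(
                f"replicate {r.replicate}: competitor signal is zero; "
                "bypass efficiency is undefined"
            )
        if control <= 0:
            raise GelError(f"replicate {r.replicate}: control signal is zero")
        value = (lesion / comp_lesion) / (control / comp_control)
        value /= r.r_lesion / r.r_control
        values.append(value * 100.0)
    return BypassResult(float(np.mean(values)), _sd(values), tuple(values))


#: Complementary-strand scheme reads N; the outcome at the lesion site is
#: complement(N).
_N_TO_M = {"A": "T", "G": "C", "T": "A", "C": "G"}
_ORDER = ("T", "C", "A", "G")


def _replicate_spectrum(run: AssayRun, lane: str = "lesion") -> MutationSpectrum:
    rows: list[np.ndarray] = []
    obs: list[float] = []
    del_fracs: dict[str, list[float]] = {"del1": [], "del2": []}

    for scheme in ("bbsi_first", "mluci_first"):
        tab = run.table(scheme, lane)
        total_products = 0.0
        per_band: dict[str, float] = {}
        for b in tab.channel_bands(lane):
            lengths = {species_length(s) for s in b.species}
            if lengths and all(l is not None and l <= PRODUCT_LENGTH for l in lengths):
                per_band[b.band_id] = per_band.get(b.band_id, 0.0) + b.intensity
                total_products += b.intensity
        if total_products <= 0:
            continue
        sub_total = sum(
            v for k, v in per_band.items() if species_length(k) == PRODUCT_LENGTH
        )
        for kind, length in (("del1", 9), ("del2", 8)):
            frac = sum(
                v for k, v in per_band.items() if species_length(k) == length
            ) / total_products
            del_fracs[kind].append(frac)
        if sub_total <= 0:
            continue
        if scheme == "bbsi_first":
            # resolved: A and G; merged: T/C
            design = {
                "10mer-A": np.array([0.0, 0.0, 1.0, 0.0]),
                "10mer-G": np.array([0.0, 0.0, 0.0, 1.0]),
                "10mer-T/C": np.array([1.0, 1.0, 0.0, 0.0]),
                "10mer-T": np.array([1.0, 1.0, 0.0, 0.0]),
                "10mer-C": np.array([1.0, 1.0, 0.0, 0.0]),
            }
        else:
            design = {
                f"10mer-{n}": np.eye(4)[_ORDER.index(m)]
                for n, m in _N_TO_M.items()
            }
        for band_id, intensity in per_band.items():
            if species_length(band_id) != PRODUCT_LENGTH:
                continue
            if band_id not in design:
                raise GelError(
                    f"band {band_id!r} has no design row under {scheme!r}"
                )
            rows.append(design[band_id])
            obs.append(intensity / sub_total)

    if not rows or all(v == 0 for v in obs):
        raise GelError("all product bands are zero; no spectrum can be solved")

    A = np.vstack(rows)
    b = np.asarray(obs)
    # simplex-constrained non-negative least squares: append a heavily
    # weighted normalization row, then renormalize exactly.
    w = 1e3
    A_aug = np.vstack([A, w * np.ones((1, 4))])
    b_aug = np.concatenate([b, [w]])
    p, _ = scipy.optimize.nnls(A_aug, b_aug)
    total = p.sum()
    if total <= 0:
        raise GelError("degenerate spectrum solution")
    p = p / total

    d1 = float(np.mean(del_fracs["del1"])) if del_fracs["del1"] else 0.0
    d2 = float(np.mean(del_fracs["del2"])) if del_fracs["del2"] else 0.0
    scale = 1.0 - d1 - d2
    return MutationSpectrum(
        f_T=p[0] * scale, f_C=p[1] * scale, f_A=p[2] * scale, f_G=p[3] * scale,
        f_del1=d1, f_del2=d2,
    )


def mutation_spectrum(run: AssayRun | Sequence[AssayRun]) -> SpectrumResult:
    """Solve the replication-product spectrum from both schemes jointly.

    f_A and f_G are constrained by both schemes' resolved bands; the T/C
    split comes from the complementary-strand scheme alone, whose N=A and
    N=G bands resolve on the gel.  Putative -1/-2 frameshift fractions come
    from 9-/8-nt bands when present.
    """
    runs = _as_runs(run)
    spectra = [_replicate_spectrum(r) for r in runs]
    arrays = np.array([s.as_array() for s in spectra])
    mean = arrays.mean(axis=0)
    sd = tuple(
        _sd(arrays[:, i].tolist()) for i in range(arrays.shape[1])
    )
    # renormalize the mean onto the simplex against float drift
    mean = mean / mean.sum()
    mean_spectrum = MutationSpectrum(*mean)
    return SpectrumResult(mean_spectrum, sd, tuple(spectra))


@dataclass(frozen=True)
class FrameshiftFlag:
    kind: str  # "-1" | "-2"
    fraction: float
    detected: bool


def detect_frameshifts(
    band_table: BandTable, threshold: float = 0.005, channel: str = "lesion"
) -> list[FrameshiftFlag]:
    """Flag putative -1/-2 frameshift bands (9/8 nt) against a detection
    threshold expressed as a fraction of the lane's labeled product signal."""
    lane_signal = sum(b.intensity for b in band_table.channel_bands(channel))
    flags: list[FrameshiftFlag] = []
    for kind, length in (("-1", 9), ("-2", 8)):
        signal = 0.0
        for b in band_table.channel_bands(channel):
            if {species_length(s) for s in b.species} == {length}:
                signal += b.intensity
        if signal <= 0:
            continue
        fraction = signal / lane_signal if lane_signal > 0 else 0.0
        flags.append(FrameshiftFlag(kind, fraction, fraction >= threshold))
    return flags


# ---------------------------------------------------------------------------
# TSV plumbing

def band_tables_frame(runs: Sequence[AssayRun]) -> pd.DataFrame:
    rows = []
    for run in runs:
        for (scheme, lane), table in sorted(run.tables.items()):
            for band in table.bands:
                rows.append(
                    {
                        "replicate": run.replicate,
                        "scheme": scheme,
                        "lane": lane,
                        "band": band.band_id,
                        "channel": band.channel,
                        "species": ";".join(band.species),
                        "intensity": band.intensity,
                        "r_lesion": run.r_lesion,
                        "r_control": run.r_control,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["replicate", "scheme", "lane", "band", "channel", "species",
                 "intensity", "r_lesion", "r_control"],
    )


def band_tables_from_frame(frame: pd.DataFrame) -> list[AssayRun]:
    runs: list[AssayRun] = []
    for replicate, group in frame.groupby("replicate"):
        tables: dict[tuple[str, str], BandTable] = {}
        for (scheme, lane), sub in group.groupby(["scheme", "lane"]):
            table = BandTable(scheme=scheme)
            for _, row in sub.iterrows():
                table.bands.append(
                    Band(
                        row["band"],
                        row["channel"],
                        tuple(str(row["species"]).split(";")),
                        float(row["intensity"]),
                    )
                )
            tables[(scheme, lane)] = table
        runs.append(
            AssayRun(
                replicate=int(replicate),
                r_lesion=float(group["r_lesion"].iloc[0]),
                r_control=float(group["r_control"].iloc[0]),
                tables=tables,
            )
        )
    return runs
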