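"""LC-MS/MS product identification for the released 10-mers.

Negative-mode ESI of the digestion products monitors the [M-3H]3- ions of
d(GGCGMGCTAT) (lesion-situated strand) and d(AATTATAGCN) (complementary
strand), M/N in {A, T, C, G}.  A candidate is scored by presence/absence of
its predicted precursor and w / a-B fragment ions in the observed peak list
within a ppm tolerance — no intensity weighting, mirroring manual ion
assignment.  The four candidates per strand have four distinct precursor
masses, so the precursor alone separates them at typical ion-trap accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from . import sequences as seqs
from .oligo_core import ODN, fragment_ladder, precursor_mz

__all__ = [
    "PeakList",
    "ProductMatch",
    "candidate_products",
    "identify_product",
    "read_peaklist_tsv",
    "write_peaklist_tsv",
    "read_peaklist_mzml",
    "matches_frame",
]

BASES = ("A", "T", "C", "G")


@dataclass(frozen=True)
class PeakList:
    """Centroided peaks (m/z, intensity) from a negative-mode spectrum."""

    peaks: tuple[tuple[float, float], ...]
    polarity: str = "negative"
    tolerance_ppm: float = 20.0

    def __post_init__(self) -> None:
        if any(mz <= 0 for mz, _ in self.peaks):
            raise ValueError("m/z values must be positive")
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("intensities must be non-negative")
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance must be positive")

    def mz_values(self) -> list[float]:
        return [mz for mz, _ in self.peaks]


@dataclass(frozen=True)
class ProductMatch:
    candidate: str  # the base occupying the variable site
    sequence: str
    precursor_match: bool
    matched: int
    predicted: int
    score: float
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")


def candidate_products(strand: str) -> list[ODN]:
    """The four candidate 10-mers for a strand ('top' or 'bottom')."""
    if strand == "top":
        template, site = seqs.TOP_PRODUCT_TEMPLATE, "M"
        return [ODN(template.format(M=b)) for b in BASES]
    if strand == "bottom":
        template = seqs.BOTTOM_PRODUCT_TEMPLATE
        return [ODN(template.format(N=b)) for b in BASES]
    raise ValueError("strand must be 'top' or 'bottom'")


def _variable_base(strand: str, sequence: str) -> str:
    pos = seqs.TOP_PRODUCT_SITE if strand == "top" else seqs.BOTTOM_PRODUCT_SITE
    return sequence[pos]


def _within(observed: Sequence[float], predicted: float, ppm: float) -> bool:
    tol = predicted * ppm * 1e-6
    return any(abs(mz - predicted) <= tol for mz in observed)


def identify_product(
    peaks: PeakList,
    strand: str,
    charge: int = 3,
    tolerance_ppm: Optional[float] = None,
    fragment_charges: Sequence[int] = (1, 2),
    ambiguity_margin: float = 0.05,
) -> list[ProductMatch]:
    """Rank the four candidate products against an observed peak list.

    The score of a candidate is the matched fraction of its predicted ions
    (precursor at the given charge plus the full w and a-B ladders at the
    fragment charge states).  Candidates whose score ties the best within
    ``ambiguity_margin`` are flagged ambiguous.
    """
    if not peaks.peaks:
        raise ValueError("empty peak list")
    tol = tolerance_ppm if tolerance_ppm is not None else peaks.tolerance_ppm
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    observed = peaks.mz_values()
    matches: list[ProductMatch] = []
    for candidate in candidate_products(strand):
        ladder = fragment_ladder(candidate, charges=tuple(fragment_charges),
                                 precursor_charge=charge)
        predicted = [ladder.precursor_mz] + ladder.mz_values()
        hits = sum(_within(observed, mz, tol) for mz in predicted)
        pre_hit = _within(observed, ladder.precursor_mz, tol)
        matches.append(
            ProductMatch(
                candidate=_variable_base(strand, candidate.bases),
                sequence=candidate.bases,
                precursor_match=bool(pre_hit),
                matched=int(hits),
                predicted=len(predicted),
                score=hits / len(predicted),
            )
        )
    matches.sort(key=lambda m: (-m.score, not m.precursor_match, m.candidate))
    best = matches[0].score
    # identification is ambiguous iff the runner-up ties the best within the
    # margin; every tying candidate (including the best) is flagged.
    tie = (best - matches[1].score) <= ambiguity_margin
    return [
        ProductMatch(
            m.candidate, m.sequence, m.precursor_match, m.matched, m.predicted,
            m.score, ambiguous=tie and (best - m.score) <= ambiguity_margin,
        )
        for m in matches
    ]


# ---------------------------------------------------------------------------
# I/O

def read_peaklist_tsv(path: str | Path, tolerance_ppm: float = 20.0) -> PeakList:
    """Two-column TSV dialect: m/z <tab> intensity (comments with #)."""
    peaks = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("m/z"):
                continue
            mz, intensity = line.split("\t")[:2]
            peaks.append((float(mz), float(intensity)))
    return PeakList(tuple(peaks), tolerance_ppm=tolerance_ppm)


def write_peaklist_tsv(peaks: PeakList, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("m/z\tintensity\n")
        for mz, intensity in peaks.peaks:
            handle.write(f"{mz:.6f}\t{intensity:.3f}\n")


def read_peaklist_mzml(path: str | Path, index: int = 0,
                       tolerance_ppm: float = 20.0) -> PeakList:
    """Read one spectrum from an mzML file (pyteomics)."""
    from pyteomics import mzml

    with mzml.read(str(path)) as reader:
        for i, spectrum in enumerate(reader):
            if i == index:
                pairs = tuple(
                    (float(mz), float(inten))
                    for mz, inten in zip(
                        spectrum["m/z array"], spectrum["intensity array"]
                    )
                )
                return PeakList(pairs, tolerance_ppm=tolerance_ppm)
    raise ValueError(f"mzML file has no spectrum with index {index}")


def matches_frame(matches: Sequence[ProductMatch], strand: str):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "strand": strand,
                "candidate": m.candidate,
                "sequence": m.sequence,
                "precursor_match": m.precursor_match,
                "matched": m.matched,
                "predicted": m.predicted,
                "score": m.score,
                "ambiguous": m.ambiguous,
            }
            for m in matches
        ]
    )
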