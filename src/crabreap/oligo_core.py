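"""Sequence and mass primitives for oligodeoxyribonucleotides (ODNs).

The assay studies O4-alkylthymidine (O4-alkyldT) adducts placed
site-specifically in short ODNs.  A lesion is written ``X`` in the base
string and carries an :class:`AdductSpec` describing the alkyl group on the
O4 position of thymine.  X pairs like its parent base T (it instructs dAMP
insertion when read correctly, dGMP when miscoding), so the Watson-Crick
complement of X is A.

Mass conventions
----------------
Monoisotopic masses are built from atomic compositions shipped in the
versioned table ``data/mass_constants.tsv``.  The neutral-molecule baseline
is the linear 5'-phosphate / 3'-OH form (sum of residue masses plus one
water); a 5'-OH terminus subtracts HPO3, a 3'-phosphate adds it, and a
5'-hexylamino modifier (the ``Y`` group on PCR primers) adds C6H13N to the
5'-phosphate.  A radiolabeled phosphate is treated at the ordinary 31P mass:
the label matters for gel visibility, not for mass arithmetic.

Fragment ions follow the standard nucleic-acid CID vocabulary (McLuckey
nomenclature): ``w`` ions retain the 3' terminus with a 5'-phosphate at the
cleaved 3' C-O bond, ``a`` ions are the complementary 5' pieces
(``a_k = M - w_{n-k}``), and ``a-B`` ions additionally lose the 3'-terminal
nucleobase of the fragment as the neutral base.  ``y``/``d`` ions (P-O5'
cleavage) are available but not predicted by default.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "ALKYL_GROUPS",
    "ISOBARIC_GROUPS",
    "CH2_MONOISOTOPIC",
    "PROTON_MASS",
    "AdductSpec",
    "ODN",
    "FragmentIon",
    "FragmentIonLadder",
    "reverse_complement",
    "ligate",
    "monoisotopic_mass",
    "precursor_mz",
    "fragment_ladder",
    "read_fasta",
    "write_fasta",
    "read_lesion_sidecar",
    "write_lesion_sidecar",
]

# Monoisotopic atomic masses (CODATA / IUPAC 2021 values).
_ELEMENT_MASS = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
}

#: Mass of a proton, used for negative-mode [M - zH]z- m/z arithmetic.
PROTON_MASS = 1.00727646688

#: Monoisotopic mass of a CH2 homologue increment.
CH2_MONOISOTOPIC = _ELEMENT_MASS["C"] + 2 * _ELEMENT_MASS["H"]

#: The eight-lesion registry: alkyl group name -> carbon count of the chain.
#: (S)/(R)-sBu differ only in stereochemistry and are isobaric.
ALKYL_GROUPS: Mapping[str, int] = {
    "Me": 1,
    "Et": 2,
    "nPr": 3,
    "iPr": 3,
    "nBu": 4,
    "iBu": 4,
    "sBu_S": 4,
    "sBu_R": 4,
}

#: Groups of registry entries with identical elemental composition.
ISOBARIC_GROUPS = (("nPr", "iPr"), ("nBu", "iBu", "sBu_S", "sBu_R"))

_FIVE_PRIME_STATES = ("OH", "phosphate", "labeled_phosphate", "amino")
_THREE_PRIME_STATES = ("OH", "phosphate")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "X": "A"}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def _formula_mass(formula: str) -> float:
    mass = 0.0
    for element, count in _FORMULA_RE.findall(formula):
        if not element:
            continue
        mass += _ELEMENT_MASS[element] * (int(count) if count else 1)
    return mass


def _load_mass_table() -> dict[tuple[str, str], float]:
    table: dict[tuple[str, str], float] = {}
    path = resources.files("crabreap").joinpath("data/mass_constants.tsv")
    with path.open() as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            kind, name, formula = row[0], row[1], row[2]
            table[(kind, name)] = _formula_mass(formula)
    return table


_MASS = _load_mass_table()
_RESIDUE = {b: _MASS[("residue", b)] for b in "ACGT"}
_BASE = {b: _MASS[("base", b)] for b in "ACGT"}
_H2O = _MASS[("group", "H2O")]
_HPO3 = _MASS[("group", "HPO3")]
_AMINOHEXYL = _MASS[("group", "AMINOHEXYL")]


@dataclass(frozen=True)
class AdductSpec:
    """An O4-alkyl adduct on thymidine.

    ``mass_shift`` is the monoisotopic mass added to the dT residue, equal to
    the mass of CnH2n for the alkyl chain (the alkyl group replaces the O4-H
    tautomeric hydrogen network only formally; compositionally an O4-alkyldT
    residue is dT + CnH2n).
    """

    alkyl_group: str
    parent_base: str = "T"
    adduct_site: str = "O4"

    def __post_init__(self) -> None:
        if self.alkyl_group not in ALKYL_GROUPS:
            raise ValueError(f"unknown alkyl group {self.alkyl_group!r}")
        if self.parent_base != "T" or self.adduct_site != "O4":
            raise ValueError("only O4 adducts on T are in the lesion registry")

    @property
    def carbons(self) -> int:
        return ALKYL_GROUPS[self.alkyl_group]

    @property
    def mass_shift(self) -> float:
        return self.carbons * CH2_MONOISOTOPIC


@dataclass(frozen=True)
class ODN:
    """A single-stranded oligodeoxyribonucleotide.

    ``bases`` uses codes A/C/G/T plus ``X`` for an annotated lesion;
    ``lesion_annotations`` maps each X position (0-based) to its
    :class:`AdductSpec`.  ``lesion_partners`` records positions whose base
    sits *opposite* a lesion on the complementary strand (an A pairing an
    O4-alkyldT), which makes reverse complementation an exact involution.
    """

    bases: str
    lesion_annotations: Mapping[int, AdductSpec] = field(default_factory=dict)
    five_prime: str = "OH"
    three_prime: str = "OH"
    lesion_partners: Mapping[int, AdductSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError("an ODN must contain at least one residue")
        bad = set(self.bases) - set("ACGTX")
        if bad:
            raise ValueError(f"unknown base code(s): {sorted(bad)}")
        if self.five_prime not in _FIVE_PRIME_STATES:
            raise ValueError(f"invalid 5' chemistry {self.five_prime!r}")
        if self.three_prime not in _THREE_PRIME_STATES:
            raise ValueError(f"invalid 3' chemistry {self.three_prime!r}")
        for pos in self.lesion_annotations:
            if not (0 <= pos < len(self.bases)) or self.bases[pos] != "X":
                raise ValueError(
                    f"lesion annotation at {pos} does not sit on an X base"
                )
        if set(i for i, b in enumerate(self.bases) if b == "X") != set(
            self.lesion_annotations
        ):
            raise ValueError("every X base requires a lesion annotation")
        object.__setattr__(self, "lesion_annotations", dict(self.lesion_annotations))
        object.__setattr__(self, "lesion_partners", dict(self.lesion_partners))

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def is_labeled(self) -> bool:
        return self.five_prime == "labeled_phosphate"

    def replaced(self, position: int, base: str) -> "ODN":
        """Return a copy with ``position`` substituted by ``base`` (lesion
        annotations at that position are dropped: replication products carry
        canonical bases)."""
        bases = self.bases[:position] + base + self.bases[position + 1 :]
        annotations = {
            p: a for p, a in self.lesion_annotations.items() if p != position
        }
        return replace(self, bases=bases, lesion_annotations=annotations)

    def slice(self, start: int, end: int, five_prime: str, three_prime: str) -> "ODN":
        if not (0 <= start < end <= len(self.bases)):
            raise ValueError(f"invalid slice [{start}, {end})")
        annotations = {
            p - start: a
            for p, a in self.lesion_annotations.items()
            if start <= p < end
        }
        partners = {
            p - start: a for p, a in self.lesion_partners.items() if start <= p < end
        }
        return ODN(
            self.bases[start:end],
            annotations,
            five_prime=five_prime,
            three_prime=three_prime,
            lesion_partners=partners,
        )


def reverse_complement(odn: ODN) -> ODN:
    """Watson-Crick reverse complement; an involution.

    X complements as its parent base T (giving A on the other strand); the
    partner position is recorded so that complementing twice restores X with
    its annotation.  5'/3' end chemistries swap roles where the vocabulary
    allows (a 5'-amino modifier has no 3' counterpart and degrades to OH).
    """
    n = len(odn.bases)
    out = []
    for b in reversed(odn.bases):
        try:
            out.append(_COMPLEMENT[b])
        except KeyError:  # pragma: no cover - guarded by ODN validation
            raise ValueError(f"unknown base code {b!r}")
    bases = "".join(out)
    partners = {n - 1 - p: a for p, a in odn.lesion_annotations.items()}
    annotations = {}
    base_list = list(bases)
    for p, a in odn.lesion_partners.items():
        q = n - 1 - p
        base_list[q] = "X"
        annotations[q] = a
    bases = "".join(base_list)
    five = odn.three_prime if odn.three_prime in _FIVE_PRIME_STATES else "OH"
    three = odn.five_prime if odn.five_prime in _THREE_PRIME_STATES else "OH"
    return ODN(bases, annotations, five_prime=five, three_prime=three,
               lesion_partners=partners)


def ligate(upstream: ODN, downstream: ODN) -> ODN:
    """Join two ODNs through a new internal phosphodiester bond.

    T4 DNA ligase chemistry requires a 5'-phosphate on the downstream strand
    and a 3'-OH on the upstream strand; the junction phosphate becomes
    internal.  Lesion annotations of the downstream ODN shift by
    ``len(upstream)``.
    """
    if downstream.five_prime not in ("phosphate", "labeled_phosphate"):
        raise ValueError("downstream ODN lacks a ligatable 5'-phosphate")
    if upstream.three_prime != "OH":
        raise ValueError("upstream ODN must end in a 3'-OH for ligation")
    shift = len(upstream)
    annotations = dict(upstream.lesion_annotations)
    annotations.update({p + shift: a for p, a in downstream.lesion_annotations.items()})
    partners = dict(upstream.lesion_partners)
    partners.update({p + shift: a for p, a in downstream.lesion_partners.items()})
    return ODN(
        upstream.bases + downstream.bases,
        annotations,
        five_prime=upstream.five_prime,
        three_prime=downstream.three_prime,
        lesion_partners=partners,
    )


def _residue_sum(odn: ODN) -> float:
    total = 0.0
    for i, b in enumerate(odn.bases):
        if b == "X":
            total += _RESIDUE["T"] + odn.lesion_annotations[i].mass_shift
        else:
            total += _RESIDUE[b]
    return total


def monoisotopic_mass(odn: ODN) -> float:
    """Neutral monoisotopic mass in Da, linear in composition."""
    mass = _residue_sum(odn) + _H2O
    if odn.five_prime == "OH":
        mass -= _HPO3
    elif odn.five_prime == "amino":
        mass += _AMINOHEXYL
    if odn.three_prime == "phosphate":
        mass += _HPO3
    return mass


def precursor_mz(odn: ODN, charge: int) -> float:
    """m/z of the [M - zH]z- anion."""
    if charge <= 0:
        raise ValueError("charge must be a positive deprotonation count")
    return (monoisotopic_mass(odn) - charge * PROTON_MASS) / charge


def _neutral_base_mass(odn: ODN, position: int) -> float:
    b = odn.bases[position]
    if b == "X":
        return _BASE["T"] + odn.lesion_annotations[position].mass_shift
    return _BASE[b]


@dataclass(frozen=True)
class FragmentIon:
    series: str
    index: int
    mz: float
    charge: int


@dataclass(frozen=True)
class FragmentIonLadder:
    precursor_mz: float
    charge: int
    ions: tuple[FragmentIon, ...]

    def mz_values(self) -> list[float]:
        return [ion.mz for ion in self.ions]


def fragment_ladder(
    odn: ODN,
    charges: Sequence[int] = (1, 2),
    series: Sequence[str] = ("w", "a-B"),
    precursor_charge: int = 3,
) -> FragmentIonLadder:
    """Predict a CID fragment-ion ladder for a deprotonated ODN.

    Every backbone position ``k = 1..n-1`` contributes one ion per requested
    series and charge state.  Neutral fragment masses satisfy
    ``a_k + w_{n-k} = M`` by construction.
    """
    n = len(odn.bases)
    if n < 2:
        raise ValueError("fragment ions require at least two residues")
    known = {"w", "a", "a-B", "y", "d"}
    bad = set(series) - known
    if bad:
        raise ValueError(f"unknown ion series: {sorted(bad)}")
    M = monoisotopic_mass(odn)
    ions: list[FragmentIon] = []
    for k in range(1, n):
        prefix = odn.slice(0, k, five_prime=odn.five_prime, three_prime="OH")
        suffix_w = odn.slice(k, n, five_prime="phosphate",
                             three_prime=odn.three_prime)
        neutral = {}
        neutral["w"] = monoisotopic_mass(suffix_w)
        neutral["a"] = M - neutral["w"]
        neutral["a-B"] = neutral["a"] - _neutral_base_mass(odn, k - 1)
        suffix_y = odn.slice(k, n, five_prime="OH", three_prime=odn.three_prime)
        neutral["y"] = monoisotopic_mass(suffix_y)
        neutral["d"] = M - neutral["y"]
        for name in series:
            # w_k / y_k count from the 3' end; a_k / d_k from the 5' end.
            index = n - k if name in ("w", "y") else k
            for z in charges:
                mz = (neutral[name] - z * PROTON_MASS) / z
                ions.append(FragmentIon(name, index, mz, z))
    pre = (M - precursor_charge * PROTON_MASS) / precursor_charge
    return FragmentIonLadder(precursor_mz=pre, charge=precursor_charge,
                             ions=tuple(ions))


# ---------------------------------------------------------------------------
# FASTA + lesion-sidecar I/O

def read_fasta(path: str | Path,
               sidecar: str | Path | None = None) -> dict[str, ODN]:
    """Read plain sequences (Biopython FASTA parser); lesion annotations come
    from an optional sidecar TSV of (sequence_id, 0-based position,
    alkyl_group)."""
    from Bio import SeqIO

    lesions: dict[str, dict[int, AdductSpec]] = {}
    if sidecar is not None:
        lesions = read_lesion_sidecar(sidecar)
    odns: dict[str, ODN] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        annotations = lesions.get(record.id, {})
        odns[record.id] = ODN(seq, annotations)
    return odns


def write_fasta(odns: Mapping[str, ODN], path: str | Path,
                sidecar: str | Path | None = None) -> None:
    with open(path, "w") as handle:
        for name, odn in odns.items():
            handle.write(f">{name}\n{odn.bases}\n")
    if sidecar is not None:
        write_lesion_sidecar(
            {name: odn.lesion_annotations for name, odn in odns.items()}, sidecar
        )


def read_lesion_sidecar(path: str | Path) -> dict[str, dict[int, AdductSpec]]:
    out: dict[str, dict[int, AdductSpec]] = {}
    with open(path) as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "sequence_id":
                continue
            seq_id, pos, group = row[0], int(row[1]), row[2]
            out.setdefault(seq_id, {})[pos] = AdductSpec(group)
    return out


def write_lesion_sidecar(
    annotations: Mapping[str, Mapping[int, AdductSpec]], path: str | Path
) -> None:
    with open(path, "w") as handle:
        handle.write("sequence_id\tposition\talkyl_group\n")
        for seq_id, table in annotations.items():
            for pos in sorted(table):
                handle.write(f"{seq_id}\t{pos}\t{table[pos].alkyl_group}\n")
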