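"""Construct assembly and sequential restriction digestion with label bookkeeping.

The assay builds a single-stranded genome by ligating a 22-mer insert into
an EcoRI-linearized vector, guided by two scaffolds whose reverse
complements each span one vector/insert junction.  After replication in
cells, PCR across the insert region yields a blunt duplex whose termini
carry 5'-hexylamino groups (unlabelable).  Sequential digestion then
selects which strand's released 10-mer is radiolabeled:

* first enzyme cuts, creating 5'-phosphates;
* shrimp alkaline phosphatase (SAP) removes all accessible 5'-phosphates;
* T4 polynucleotide kinase (PNK) labels every free 5'-OH;
* the second enzyme cuts, creating fresh *unlabeled* 5'-phosphates.

Hence labels mark exactly the 5' termini created by the first digestion:
BbsI-first labels the lesion-strand d(p*GGCGMGCTAT); MluCI-first labels the
complementary-strand d(p*AATTATAGCN).

Coordinates are 0-based, half-open, in the top-strand frame; cut positions
are between-base indices.  Enzyme geometry (REBASE): EcoRI G^AATTC, MluCI
^AATT, BbsI GAAGAC(2/6).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import sequences as seqs
from .oligo_core import ODN, reverse_complement

__all__ = [
    "AssemblyError",
    "AmpliconError",
    "SchemeError",
    "RestrictionEnzyme",
    "CutSite",
    "DuplexRegion",
    "GenomeConstruct",
    "LabeledFragment",
    "AssayScheme",
    "BBSI_FIRST",
    "MLUCI_FIRST",
    "load_enzyme_table",
    "default_enzymes",
    "find_sites",
    "assemble_construct",
    "extract_amplicon",
    "enumerate_outcomes",
    "sequential_digest_label",
    "fragments_frame",
]


class AssemblyError(ValueError):
    """A scaffold fails to bridge a vector/insert junction."""


class AmpliconError(ValueError):
    """Primer matching failed or the template still carries a lesion."""


class SchemeError(ValueError):
    """A digestion/labeling scheme is missing a required step."""


def _dna(s: str) -> str:
    """Hybridization view of a sequence: a lesion base pairs like T."""
    return s.replace("X", "T")


_RC = str.maketrans("ACGTX", "TGCAA")


def _rc_str(s: str) -> str:
    return _dna(s).translate(_RC)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Recognition sequence plus cut offsets in the top-strand frame.

    ``top_cut``/``bottom_cut`` are between-base indices relative to the
    recognition start when the site is read on the top strand; the same
    geometry is mirrored for bottom-strand sites, which for a Type IIS
    cutter like BbsI places the cuts 5' of the recognition sequence.
    """

    name: str
    recognition: str
    top_cut: int
    bottom_cut: int
    sensitive_to_recognition_loss: bool = True

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("recognition sequence must be non-empty")

    @property
    def overhang(self) -> int:
        """Positive for 5' overhangs, negative for 3', zero for blunt."""
        return self.bottom_cut - self.top_cut

    @property
    def is_palindromic(self) -> bool:
        return _rc_str(self.recognition) == self.recognition


@dataclass(frozen=True)
class CutSite:
    enzyme: str
    strand: str  # strand carrying the recognition sequence
    rec_start: int
    rec_end: int
    top_cut: int
    bottom_cut: int


def load_enzyme_table(path: str | Path) -> dict[str, RestrictionEnzyme]:
    table: dict[str, RestrictionEnzyme] = {}
    with open(path) as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "name":
                continue
            name, recognition, top_cut, bottom_cut = row[:4]
            table[name] = RestrictionEnzyme(
                name, recognition.upper(), int(top_cut), int(bottom_cut)
            )
    return table


def default_enzymes() -> dict[str, RestrictionEnzyme]:
    path = resources.files("crabreap").joinpath("data/enzymes.tsv")
    with resources.as_file(path) as p:
        return load_enzyme_table(p)


# ---------------------------------------------------------------------------
# Duplexes and constructs

@dataclass(frozen=True)
class DuplexRegion:
    """A blunt double-stranded region in the top-strand coordinate frame.

    ``bottom`` is stored 5'->3' (its residue j pairs top residue
    ``n - 1 - j``).  ``site`` is the top-frame coordinate of the replication
    -product position, if one exists; ``outcome`` the base inserted there.
    """

    top: ODN
    bottom: ODN
    site: Optional[int] = None
    channel: str = "lesion"
    outcome: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.top) != len(self.bottom):
            raise ValueError("duplex strands differ in length")
        if _dna(self.bottom.bases) != _rc_str(self.top.bases):
            raise ValueError("bottom strand is not the reverse complement")
        if self.site is not None and not (0 <= self.site < len(self.top)):
            raise ValueError("site outside duplex")

    def __len__(self) -> int:
        return len(self.top)

    @classmethod
    def from_top(
        cls,
        top: ODN,
        site: Optional[int] = None,
        channel: str = "lesion",
        outcome: Optional[str] = None,
    ) -> "DuplexRegion":
        bottom = reverse_complement(top)
        return cls(top, bottom, site=site, channel=channel, outcome=outcome)


@dataclass(frozen=True)
class GenomeConstruct:
    """Insert plus scaffold-defined vector flanks for one channel.

    The amplicon-relevant region reads ``upstream_flank + insert +
    downstream_flank``.  ``site_in_insert`` locates the lesion (or the
    corresponding T of the control) within the insert.
    """

    insert: ODN
    upstream_flank: ODN
    downstream_flank: ODN
    channel: str
    site_in_insert: Optional[int] = None
    upstream_overlap: int = 0
    downstream_overlap: int = 0

    @property
    def region(self) -> str:
        return (
            self.upstream_flank.bases + self.insert.bases + self.downstream_flank.bases
        )

    @property
    def site(self) -> Optional[int]:
        if self.site_in_insert is None:
            return None
        return len(self.upstream_flank) + self.site_in_insert


def assemble_construct(
    insert: ODN,
    scaffold1: ODN,
    scaffold2: ODN,
    vector_context: Optional[Mapping[str, str]] = None,
    channel: str = "lesion",
    site_in_insert: Optional[int] = None,
    min_overlap: int = 4,
) -> GenomeConstruct:
    """Scaffold-guided ligation of the insert into the linearized vector.

    Each scaffold's reverse complement must span one junction: a suffix of
    the upstream flank followed by a prefix of the insert (scaffold 1), and
    a suffix of the insert followed by a prefix of the downstream flank
    (scaffold 2).  The flank sequences are read off the scaffold reverse
    complements, extended by optional vector context
    ``{"upstream": ..., "downstream": ...}``.
    """
    if insert.five_prime not in ("phosphate", "labeled_phosphate"):
        raise AssemblyError("insert must be 5'-phosphorylated for ligation")
    rc1 = _rc_str(scaffold1.bases)
    rc2 = _rc_str(scaffold2.bases)
    ins = _dna(insert.bases)

    up_k = 0
    for k in range(min(len(rc1) - 1, len(ins)), min_overlap - 1, -1):
        if rc1[-k:] == ins[:k]:
            up_k = k
            break
    if not up_k:
        raise AssemblyError(
            "upstream junction: scaffold 1 reverse complement does not bridge "
            "the vector end and the insert 5' end"
        )
    down_m = 0
    for m in range(min(len(rc2) - 1, len(ins)), min_overlap - 1, -1):
        if rc2[:m] == ins[-m:]:
            down_m = m
            break
    if not down_m:
        raise AssemblyError(
            "downstream junction: scaffold 2 reverse complement does not bridge "
            "the insert 3' end and the vector start"
        )

    context = vector_context or {}
    upstream = context.get("upstream", seqs.DEFAULT_UPSTREAM_CONTEXT) + rc1[:-up_k]
    downstream = rc2[down_m:] + context.get(
        "downstream", seqs.DEFAULT_DOWNSTREAM_CONTEXT
    )

    if site_in_insert is None:
        xs = [i for i, b in enumerate(insert.bases) if b == "X"]
        if len(xs) == 1:
            site_in_insert = xs[0]
        elif channel == "control" and _dna(insert.bases) == _dna(
            seqs.UPSTREAM_10MER + seqs.CONTROL_12MER
        ):
            site_in_insert = seqs.LESION_SITE_IN_22MER
    if channel == "lesion" and "X" not in insert.bases:
        raise AssemblyError("lesion channel requires a lesion-bearing insert")

    return GenomeConstruct(
        insert=insert,
        upstream_flank=ODN(upstream),
        downstream_flank=ODN(downstream),
        channel=channel,
        site_in_insert=site_in_insert,
        upstream_overlap=up_k,
        downstream_overlap=down_m,
    )


def _strip_modifier(primer: str) -> str:
    return "".join(b for b in primer.upper() if b in "ACGT")


def _locate_primer(region: str, primer: str, anchor: int, name: str) -> int:
    """Return the region index where the primer's 5' end aligns.

    Matching is anchored on the primer's 3'-terminal ``anchor`` bases (the
    extension-critical end); the PCR product inherits the full primer
    sequence, so 5'-terminal modifier bases or mismatches do not move the
    product boundary.
    """
    a = min(anchor, len(primer))
    probe = primer[-a:]
    count = region.count(probe)
    if count == 0:
        raise AmpliconError(f"{name} primer has no binding site")
    if count > 1:
        raise AmpliconError(f"{name} primer binds at {count} sites")
    return region.index(probe) - (len(primer) - a)


def extract_amplicon(
    construct: GenomeConstruct,
    fwd_primer: str | ODN = seqs.FWD_PRIMER,
    rev_primer: str | ODN = seqs.REV_PRIMER,
    anchor: int = 15,
) -> DuplexRegion:
    """Realize the primer-bounded PCR duplex (exact amplification model).

    The template must not contain a lesion base: lesions exist only in the
    input genome, and replication (``enumerate_outcomes``) resolves them to
    canonical bases before any PCR.
    """
    region = construct.region
    if "X" in region:
        raise AmpliconError(
            "template still carries a lesion; enumerate replication outcomes first"
        )
    fwd = _strip_modifier(fwd_primer if isinstance(fwd_primer, str) else fwd_primer.bases)
    rev = _strip_modifier(rev_primer if isinstance(rev_primer, str) else rev_primer.bases)
    rc_rev = _rc_str(rev)

    start = _locate_primer(region, fwd, anchor, "forward")
    # the reverse primer anneals to the top strand; its 3' end maps to the
    # left end of rc(rev) on the top strand, so anchor on rc_rev's prefix.
    a = min(anchor, len(rc_rev))
    probe = rc_rev[:a]
    count = region.count(probe)
    if count == 0:
        raise AmpliconError("reverse primer has no binding site")
    if count > 1:
        raise AmpliconError(f"reverse primer binds at {count} sites")
    q0 = region.index(probe)
    end = q0 + len(rc_rev)
    if start < 0 or end > len(region) or q0 < start + len(fwd):
        raise AmpliconError("primer sites do not bound a well-formed amplicon")

    top_seq = fwd + region[start + len(fwd) : q0] + rc_rev
    site = None
    outcome = None
    if construct.site is not None:
        site = construct.site - start
        if not (0 <= site < len(top_seq)):
            raise AmpliconError("replication-product site falls outside amplicon")
        outcome = top_seq[site]
    top = ODN(top_seq, five_prime="amino")
    bottom = ODN(_rc_str(top_seq), five_prime="amino")
    return DuplexRegion(top, bottom, site=site, channel=construct.channel,
                        outcome=outcome)


def _delete_positions(odn: ODN, positions: Sequence[int]) -> ODN:
    keep = [b for i, b in enumerate(odn.bases) if i not in set(positions)]
    return ODN("".join(keep), five_prime=odn.five_prime,
               three_prime=odn.three_prime)


def enumerate_outcomes(
    construct: GenomeConstruct,
    include_deletions: bool = False,
    fwd_primer: str | ODN = seqs.FWD_PRIMER,
    rev_primer: str | ODN = seqs.REV_PRIMER,
) -> list[DuplexRegion]:
    """The four potential replication products at the lesion site.

    Each outcome substitutes M in {T, C, A, G} at the site (replication
    replaces the lesion by a canonical base) and realizes the PCR duplex.
    With ``include_deletions``, putative -1 and -2 frameshift products
    (deleting the site base, or the site base and its 3' neighbour) are
    appended with outcomes ``del1``/``del2``.
    """
    if construct.site_in_insert is None:
        raise ValueError("construct has no replication-product position")
    pos = construct.site_in_insert
    out: list[DuplexRegion] = []
    for m in "TCAG":
        progeny = replace(construct, insert=construct.insert.replaced(pos, m))
        out.append(extract_amplicon(progeny, fwd_primer, rev_primer))
    if include_deletions:
        for label, dropped in (("del1", [pos]), ("del2", [pos, pos + 1])):
            shrunk = _delete_positions(construct.insert, dropped)
            progeny = replace(construct, insert=shrunk, site_in_insert=None)
            duplex = extract_amplicon(progeny, fwd_primer, rev_primer)
            out.append(replace(duplex, outcome=label))
    return out


# ---------------------------------------------------------------------------
# Digestion

def find_sites(duplex: DuplexRegion, enzyme: RestrictionEnzyme) -> list[CutSite]:
    """All recognition occurrences on either strand with resolved cut
    coordinates (top-strand frame).  Sites whose cuts would fall outside the
    duplex do not cleave and are omitted; palindromic sites are reported
    once."""
    top = _dna(duplex.top.bases)
    n = len(top)
    rec = enzyme.recognition
    rc_rec = _rc_str(rec)
    L = len(rec)
    sites: list[CutSite] = []
    seen: set[tuple[int, int]] = set()

    def _add(strand: str, i: int, top_cut: int, bottom_cut: int) -> None:
        if not (0 < top_cut < n and 0 < bottom_cut < n):
            return
        key = (top_cut, bottom_cut)
        if key in seen:
            return
        seen.add(key)
        sites.append(CutSite(enzyme.name, strand, i, i + L, top_cut, bottom_cut))

    for i in range(n - L + 1):
        if top[i : i + L] == rec:
            _add("top", i, i + enzyme.top_cut, i + enzyme.bottom_cut)
        if top[i : i + L] == rc_rec:
            _add("bottom", i, i + L - enzyme.bottom_cut, i + L - enzyme.top_cut)
    sites.sort(key=lambda s: (s.top_cut, s.bottom_cut))
    return sites


@dataclass(frozen=True)
class AssayScheme:
    """Named digestion/labeling order: first enzyme, SAP, PNK, second enzyme."""

    name: str
    first_enzyme: str
    second_enzyme: str
    dephosphorylate: bool = True
    label: bool = True

    def validate(self) -> None:
        missing = []
        if not self.first_enzyme:
            missing.append("first digestion")
        if not self.dephosphorylate:
            missing.append("dephosphorylation (SAP)")
        if not self.label:
            missing.append("labeling (PNK)")
        if not self.second_enzyme:
            missing.append("second digestion")
        if missing:
            raise SchemeError(
                f"scheme {self.name!r} is missing required step(s): "
                + ", ".join(missing)
            )


#: The two printed schemes: BbsI-first labels the lesion-bearing strand,
#: MluCI-first the complementary strand.
BBSI_FIRST = AssayScheme("bbsi_first", "BbsI", "MluCI")
MLUCI_FIRST = AssayScheme("mluci_first", "MluCI", "BbsI")


@dataclass(frozen=True)
class LabeledFragment:
    """A digestion product of one strand with its 5'-label state."""

    sequence: ODN
    strand: str  # top | bottom
    start: int  # top-frame coordinates, half-open
    end: int
    five_prime_label: bool
    origin_channel: str
    site_base: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("fragment end must exceed start")

    def __len__(self) -> int:
        return self.end - self.start


def sequential_digest_label(
    duplex: DuplexRegion,
    scheme: AssayScheme,
    enzymes: Optional[Mapping[str, RestrictionEnzyme]] = None,
    visible_only: bool = False,
) -> list[LabeledFragment]:
    """Run first-digest -> SAP -> PNK -> second-digest on a duplex.

    Returns per-strand fragments with ``five_prime_label`` true exactly on
    5' termini created by the first digestion.  ``visible_only`` restricts
    the output to the gel-visible (labeled) set.
    """
    scheme.validate()
    enzymes = enzymes if enzymes is not None else default_enzymes()
    for name in (scheme.first_enzyme, scheme.second_enzyme):
        if name not in enzymes:
            raise SchemeError(f"scheme {scheme.name!r} names unknown enzyme {name!r}")
    n = len(duplex)
    # segments: (start, end, five_prime_state); a bottom segment's 5' end
    # sits at its *end* coordinate (top frame).
    top_segs = [(0, n, duplex.top.five_prime)]
    bot_segs = [(0, n, duplex.bottom.five_prime)]

    def _digest(enz: RestrictionEnzyme) -> None:
        nonlocal top_segs, bot_segs
        cuts = find_sites(duplex, enz)
        for c in sorted({s.top_cut for s in cuts}):
            new = []
            for s, e, state in top_segs:
                if s < c < e:
                    new.append((s, c, state))
                    new.append((c, e, "phosphate"))
                else:
                    new.append((s, e, state))
            top_segs = new
        for c in sorted({s.bottom_cut for s in cuts}):
            new = []
            for s, e, state in bot_segs:
                if s < c < e:
                    new.append((c, e, state))
                    new.append((s, c, "phosphate"))
                else:
                    new.append((s, e, state))
            bot_segs = new

    def _sap() -> None:
        nonlocal top_segs, bot_segs
        strip = lambda st: "OH" if st in ("phosphate", "labeled_phosphate") else st
        top_segs = [(s, e, strip(st)) for s, e, st in top_segs]
        bot_segs = [(s, e, strip(st)) for s, e, st in bot_segs]

    def _pnk() -> None:
        nonlocal top_segs, bot_segs
        mark = lambda st: "labeled_phosphate" if st == "OH" else st
        top_segs = [(s, e, mark(st)) for s, e, st in top_segs]
        bot_segs = [(s, e, mark(st)) for s, e, st in bot_segs]

    _digest(enzymes[scheme.first_enzyme])
    _sap()
    _pnk()
    _digest(enzymes[scheme.second_enzyme])

    fragments: list[LabeledFragment] = []
    for s, e, state in sorted(top_segs):
        odn = duplex.top.slice(s, e, five_prime=state,
                               three_prime=duplex.top.three_prime if e == n else "OH")
        base = (
            duplex.top.bases[duplex.site]
            if duplex.site is not None and s <= duplex.site < e
            else None
        )
        fragments.append(
            LabeledFragment(odn, "top", s, e, state == "labeled_phosphate",
                            duplex.channel, base)
        )
    for s, e, state in sorted(bot_segs):
        odn = duplex.bottom.slice(
            n - e, n - s, five_prime=state,
            three_prime=duplex.bottom.three_prime if s == 0 else "OH",
        )
        base = (
            duplex.bottom.bases[n - 1 - duplex.site]
            if duplex.site is not None and s <= duplex.site < e
            else None
        )
        fragments.append(
            LabeledFragment(odn, "bottom", s, e, state == "labeled_phosphate",
                            duplex.channel, base)
        )
    if visible_only:
        fragments = [f for f in fragments if f.five_prime_label]
    return fragments


def fragments_frame(
    fragments: Iterable[LabeledFragment], scheme: AssayScheme
) -> pd.DataFrame:
    """Tabulate fragments as the TSV dialect used throughout the pipeline."""
    rows = [
        {
            "channel": f.origin_channel,
            "scheme": scheme.name,
            "strand": f.strand,
            "start": f.start,
            "end": f.end,
            "sequence": f.sequence.bases,
            "labeled": f.five_prime_label,
            "site_base": f.site_base if f.site_base is not None else "",
        }
        for f in fragments
    ]
    return pd.DataFrame(
        rows,
        columns=["channel", "scheme", "strand", "start", "end", "sequence",
                 "labeled", "site_base"],
    )
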