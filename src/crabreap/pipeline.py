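"""End-to-end pipeline: assemble -> outcomes -> digest -> bands -> quantify -> verify.

`run_pipeline` ties the stages together deterministically and writes
diff-friendly TSV tables plus a provenance record (config hash, seed,
version).  Stage failures propagate as :class:`PipelineError` naming the
stage and the offending record.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from . import sequences as seqs
from .construct_digest import (
    BBSI_FIRST,
    MLUCI_FIRST,
    assemble_construct,
    default_enzymes,
    enumerate_outcomes,
    extract_amplicon,
    fragments_frame,
    load_enzyme_table,
    sequential_digest_label,
)
from .gel_quant import (
    band_tables_frame,
    bypass_efficiency,
    default_comigration_rules,
    load_comigration_rules,
    mutation_spectrum,
)
from .ms_verify import identify_product, matches_frame
from .oligo_core import ODN, ligate
from .synthetic_data import (
    generate_peaklist,
    generate_run,
    load_scenarios,
    scenario_ground_truth,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "build_constructs"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Paths left ``None`` fall back to the packaged enzyme table, co-migration
    rules and scenario presets.
    """

    outdir: str = "results"
    seed: int = 0
    alkyl_group: str = "Et"
    scenarios: Optional[Sequence[str]] = None
    enzyme_table: Optional[str] = None
    comigration: Optional[str] = None
    ms_jitter_ppm: float = 5.0
    ms_decoys: int = 5
    include_deletions: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown option(s): {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location and logging
        verbosity excluded: they do not affect any computed number)."""
        payload = asdict(self)
        payload.pop("outdir", None)
        payload.pop("log_level", None)
        blob = yaml.safe_dump(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def build_constructs(alkyl_group: str):
    """Assemble the lesion, control and (synthetic) competitor constructs
    from the printed oligos."""
    upstream = ODN(seqs.UPSTREAM_10MER)
    lesion_insert = ligate(upstream, seqs.lesion_12mer(alkyl_group,
                                                       five_prime="phosphate"))
    control_insert = ligate(upstream, seqs.control_12mer(five_prime="phosphate"))
    scaffold1, scaffold2 = ODN(seqs.SCAFFOLD_1), ODN(seqs.SCAFFOLD_2)
    # the 22-mers carry a 5'-OH after PAGE purification; the vector ligation
    # step requires the 5'-phosphate restored
    lesion_insert = ODN(lesion_insert.bases, lesion_insert.lesion_annotations,
                        five_prime="phosphate")
    control_insert = ODN(control_insert.bases, five_prime="phosphate")
    competitor_insert = ODN(seqs.SYNTHETIC_COMPETITOR_INSERT,
                            five_prime="phosphate")
    lesion = assemble_construct(lesion_insert, scaffold1, scaffold2,
                                channel="lesion")
    control = assemble_construct(control_insert, scaffold1, scaffold2,
                                 channel="control")
    competitor = assemble_construct(competitor_insert, scaffold1, scaffold2,
                                    channel="competitor")
    return lesion, control, competitor


def _float_fmt(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle under ``config.outdir``.

    Returns a summary dict with the per-scenario quantification.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- resources -------------------------------------------------------
    if config.enzyme_table is not None:
        if not Path(config.enzyme_table).exists():
            raise PipelineError("config",
                                f"enzyme table not found: {config.enzyme_table}")
        enzymes = load_enzyme_table(config.enzyme_table)
    else:
        enzymes = default_enzymes()
    if config.comigration is not None:
        if not Path(config.comigration).exists():
            raise PipelineError("config",
                                f"co-migration rules not found: {config.comigration}")
        rules = load_comigration_rules(config.comigration)
    else:
        rules = default_comigration_rules()

    # --- assembly --------------------------------------------------------
    try:
        lesion, control, competitor = build_constructs(config.alkyl_group)
    except Exception as exc:
        raise PipelineError("assemble", str(exc)) from exc

    # --- outcomes + digestion -------------------------------------------
    frames = []
    try:
        duplexes = [
            (extract_amplicon(control), "control"),
            (extract_amplicon(competitor), "competitor"),
        ]
        for duplex in enumerate_outcomes(lesion,
                                         include_deletions=config.include_deletions):
            duplexes.append((duplex, f"M={duplex.outcome}"))
        for scheme in (BBSI_FIRST, MLUCI_FIRST):
            for duplex, label in duplexes:
                fragments = sequential_digest_label(duplex, scheme, enzymes)
                frame = fragments_frame(fragments, scheme)
                frame.insert(0, "outcome", label)
                frames.append(frame)
    except Exception as exc:
        raise PipelineError("digest", str(exc)) from exc
    fragment_table = pd.concat(frames, ignore_index=True)
    _float_fmt(fragment_table, outdir / "fragments.tsv")

    # --- simulation + quantification ------------------------------------
    scenarios = load_scenarios()
    names = list(config.scenarios) if config.scenarios else list(scenarios)
    band_frames = []
    quant_rows = []
    for i, name in enumerate(names):
        try:
            gt = scenario_ground_truth(name, seed=(config.seed * 1009 + i) % (2**31),
                                       scenarios=scenarios)
            runs = generate_run(gt, rules)
            bands = band_tables_frame(runs)
            bands.insert(0, "scenario", name)
            band_frames.append(bands)
            bypass = bypass_efficiency(runs)
            spectrum = mutation_spectrum(runs)
            quant_rows.append(
                {
                    "scenario": name,
                    "bypass_mean_pct": bypass.mean,
                    "bypass_sd_pct": bypass.sd,
                    "mf_mean_pct": spectrum.mutation_frequency_mean * 100.0,
                    "mf_sd_pct": spectrum.mutation_frequency_sd * 100.0,
                    "f_T": spectrum.mean.f_T,
                    "f_C": spectrum.mean.f_C,
                    "f_A": spectrum.mean.f_A,
                    "f_G": spectrum.mean.f_G,
                    "true_bypass_pct": gt.bypass * 100.0,
                    "true_mf_pct": (1.0 - gt.spectrum[0]) * 100.0,
                }
            )
        except Exception as exc:
            raise PipelineError("quantify", f"scenario {name!r}: {exc}") from exc
    _float_fmt(pd.concat(band_frames, ignore_index=True), outdir / "bands.tsv")
    quant_table = pd.DataFrame(quant_rows)
    _float_fmt(quant_table, outdir / "quantification.tsv")

    # --- MS verification --------------------------------------------------
    try:
        ms_frames = []
        pairs = (("top", "GGCGCGCTAT"), ("bottom", "AATTATAGCG"))
        for j, (strand, product) in enumerate(pairs):
            peaks = generate_peaklist(
                ODN(product), ppm_jitter=config.ms_jitter_ppm,
                seed=(config.seed * 7919 + j) % (2**31),
                n_decoys=config.ms_decoys,
            )
            matches = identify_product(peaks, strand)
            ms_frames.append(matches_frame(matches, strand))
        ms_table = pd.concat(ms_frames, ignore_index=True)
        _float_fmt(ms_table, outdir / "ms_matches.tsv")
    except Exception as exc:
        raise PipelineError("msid", str(exc)) from exc

    # --- provenance ------------------------------------------------------
    provenance = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
        "scenarios": names,
    }
    with open(outdir / "provenance.yaml", "w") as handle:
        yaml.safe_dump(provenance, handle, sort_keys=True)

    return {
        "quantification": quant_table,
        "fragments": fragment_table,
        "ms_matches": ms_table,
        "provenance": provenance,
    }
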