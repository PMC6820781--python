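"""Pipeline configuration and end-to-end orchestration."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .combing import cohort_summary, read_measurements
from .decompose import decompose_read, summarize_reads
from .io import read_sequences, write_fastq
from .locus import LocusConfig, default_locus
from .phenostats import onset_correlation_report
from .screen import genotype_locus
from .simulate import (ExpansionModel, ReadErrorModel, emit_cohort,
                       emit_combing_table, emit_long_reads, emit_short_reads,
                       simulate_allele_population)

log = logging.getLogger("famex")


class PipelineConfigError(ValueError):
    pass


_KNOWN_KEYS = {"locus", "seed", "outdir", "log_level", "simulate", "decompose",
               "screen", "comb", "correlate"}
_KNOWN_SIM_KEYS = {"n_cells", "n_long_reads", "short_read_coverage",
                   "germline", "somatic_cv", "error_model", "n_individuals",
                   "p_truncate"}


@dataclass
class PipelineConfig:
    """Validated run configuration; unknown keys are rejected."""

    locus: LocusConfig
    seed: int = 1
    outdir: Path = Path("famex_out")
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    decompose: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)
    comb: dict = field(default_factory=dict)
    correlate: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        sim = raw.get("simulate", {})
        if unknown := set(sim) - _KNOWN_SIM_KEYS:
            raise PipelineConfigError(f"unknown simulate keys: {sorted(unknown)}")
        locus_spec = raw.get("locus")
        if locus_spec is None:
            locus = default_locus()
        elif isinstance(locus_spec, str):
            locus = LocusConfig.from_json(locus_spec)
        else:
            locus = LocusConfig.from_dict(locus_spec)
        return cls(locus=locus, seed=int(raw.get("seed", 1)),
                   outdir=Path(raw.get("outdir", "famex_out")),
                   log_level=raw.get("log_level", "INFO"),
                   simulate=sim,
                   decompose=raw.get("decompose", {}),
                   screen=raw.get("screen", {}),
                   comb=raw.get("comb", {}),
                   correlate=raw.get("correlate", {}))

    def config_hash(self) -> str:
        payload = json.dumps({
            "locus": self.locus.to_dict(), "seed": self.seed,
            "simulate": self.simulate, "decompose": self.decompose,
            "screen": self.screen, "comb": self.comb,
            "correlate": self.correlate,
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> decompose -> screen -> comb -> correlate.

    Writes every stage's TSV into the output directory plus a manifest
    recording the config hash, seed, package version, and the stages that
    completed. On stage failure, partial outputs are retained and the
    manifest records the failure point before the exception propagates.
    """
    logging.basicConfig(level=config.log_level,
                        format="%(name)s %(levelname)s %(message)s")
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": [],
        "failed_stage": None,
    }
    sim = config.simulate
    germline = tuple(sim.get("germline", (600, 400, 100)))
    model = ExpansionModel(germline=germline,
                           somatic_cv=float(sim.get("somatic_cv", 0.25)))
    err = ReadErrorModel(**sim.get("error_model", {}))

    def _write_manifest() -> None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    try:
        stage = "simulate"
        log.info("stage: %s", stage)
        cells = simulate_allele_population(model, int(sim.get("n_cells", 200)),
                                           seed=config.seed)
        cells.to_csv(out / "cells.tsv", sep="\t", index=False)
        long_reads, truth = emit_long_reads(
            cells, config.locus, err, n_reads=int(sim.get("n_long_reads", 30)),
            seed=config.seed + 1, p_truncate=float(sim.get("p_truncate", 0.1)))
        write_fastq(long_reads, out / "long_reads.fastq")
        truth.to_csv(out / "long_read_truth.tsv", sep="\t", index=False)
        r1, r2 = emit_short_reads(cells, config.locus,
                                  coverage=float(sim.get("short_read_coverage", 20)),
                                  seed=config.seed + 2)
        write_fastq(r1, out / "short_R1.fastq")
        write_fastq(r2, out / "short_R2.fastq")
        comb_table = emit_combing_table(cells, seed=config.seed + 3, p_truncate=0.05)
        comb_table.to_csv(out / "combing.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "decompose"
        log.info("stage: %s", stage)
        decomposed = [decompose_read(rid, seq, config.locus, **config.decompose)
                      for rid, seq, _ in read_sequences(out / "long_reads.fastq")]
        decomp_frame(decomposed).to_csv(out / "decomposition.tsv", sep="\t",
                                        index=False)
        summary = summarize_reads(decomposed)
        pd.DataFrame([summary.__dict__]).to_csv(out / "nanopore_summary.tsv",
                                                sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "screen"
        log.info("stage: %s", stage)
        reads = [seq for _, seq, _ in read_sequences(out / "short_R1.fastq")]
        reads += [seq for _, seq, _ in read_sequences(out / "short_R2.fastq")]
        result = genotype_locus(reads, config.locus, **config.screen)
        screen_frame(result).to_csv(out / "screen.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "comb"
        log.info("stage: %s", stage)
        alleles = read_measurements(out / "combing.tsv")
        cohort_summary(alleles, **config.comb).to_csv(out / "combing_summary.tsv",
                                                      sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "correlate"
        log.info("stage: %s", stage)
        cohort = emit_cohort(int(sim.get("n_individuals", 10)),
                             seed=config.seed + 4)
        cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
        report = onset_correlation_report(cohort, **config.correlate)
        report.to_csv(out / "correlations.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)
    except Exception:
        manifest["failed_stage"] = stage
        _write_manifest()
        raise
    _write_manifest()
    return manifest


def decomp_frame(decomposed) -> pd.DataFrame:
    """Per-read decomposition TSV rows."""
    return pd.DataFrame([{
        "read_id": d.read_id,
        "orientation": d.orientation,
        "coverage": d.coverage,
        "n_units_TTTTA_5p": d.units_5p,
        "n_units_TTTCA": d.units_mid,
        "n_units_TTTTA_3p": d.units_3p,
        "n_gaps": len(d.structure.gaps),
        "size_kb_total": round(d.size_kb_total, 3),
        "size_kb_TTTTA_5p": round(d.size_kb_5p, 3),
        "size_kb_TTTCA": round(d.size_kb_mid, 3),
        "size_kb_TTTTA_3p": round(d.size_kb_3p, 3),
        "structure_string": d.structure.structure_string(),
    } for d in decomposed])


def screen_frame(result) -> pd.DataFrame:
    alleles = ";".join(
        ("(%s)%s" % (",".join(f"{m}:{c}" for m, c in a.unit_counts.items()),
                     ">lb" if a.lower_bound else ""))
        for a in result.allele_estimates)
    return pd.DataFrame([{
        "locus_id": result.locus_id,
        "n_spanning_reads": result.n_spanning_reads,
        "n_anchored_inrepeat_reads": result.n_anchored_inrepeat_reads,
        "n_fully_inrepeat_reads": result.n_fully_inrepeat_reads,
        "allele_estimates": alleles,
        "no_coverage": int(result.no_coverage),
        **{f"call_{m}": int(v) for m, v in result.expansion_call.items()},
    }])
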