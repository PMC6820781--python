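"""Synthetic data generation for every pipeline stage.

Emulates mixed 5'-(TTTTA)exp(TTTCA)exp(TTTTA)opt-3' alleles with per-cell
somatic mosaicism, size-dependent micro-rearrangement, long-read
base-calling errors, 150-bp paired short reads, combing signal noise, and
a seizure-onset phenotype inversely related to the middle-motif length.
All randomness flows from one explicit seed through a named generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .locus import LocusConfig, default_locus
from .sequence import reverse_complement

BASES = np.array(list("ACGT"))

CONFIG_LABELS = ("C1", "C2", "C3", "C4", "C5", "C6")


@dataclass(frozen=True)
class ExpansionModel:
    """Germline allele structure and somatic instability model.

    ``germline`` gives the expanded allele's unit counts (5' first motif,
    middle motif, 3' first motif); per-cell counts are jittered by a
    log-normal factor with coefficient of variation ``somatic_cv``.
    Rearrangement probability is a scaled logistic in the cell's expansion
    size: ``rearrange_max / (1 + exp(-(size - midpoint)/slope))``.
    """

    germline: tuple[int, int, int] = (600, 400, 100)
    normal_units: int = 12
    somatic_cv: float = 0.25
    config_mix: dict[str, float] = field(default_factory=lambda: {
        "C1": 0.30, "C2": 0.40, "C3": 0.12, "C4": 0.08, "C5": 0.05, "C6": 0.05,
    })
    rearrange_midpoint_kb: float = 12.0
    rearrange_slope_kb: float = 3.0
    rearrange_max: float = 0.15

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.germline):
            raise ValueError("germline unit counts must be >= 0")
        total = sum(self.config_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"config_mix probabilities sum to {total}, not 1")
        if unknown := set(self.config_mix) - set(CONFIG_LABELS):
            raise ValueError(f"unknown configuration labels: {sorted(unknown)}")

    def p_rearrange(self, size_kb: float) -> float:
        z = (size_kb - self.rearrange_midpoint_kb) / self.rearrange_slope_kb
        return self.rearrange_max / (1.0 + math.exp(-z))


@dataclass(frozen=True)
class ReadErrorModel:
    substitution: float = 0.03
    insertion: float = 0.03
    deletion: float = 0.04

    def __post_init__(self) -> None:
        for name, rate in (("substitution", self.substitution),
                           ("insertion", self.insertion),
                           ("deletion", self.deletion)):
            if not 0 <= rate <= 0.2:
                raise ValueError(f"{name} rate {rate} outside [0, 0.2]")

    @property
    def total(self) -> float:
        return self.substitution + self.insertion + self.deletion


@dataclass(frozen=True)
class PhenotypeModel:
    """Seizure onset decreases linearly with middle-motif kb; tremor does not."""

    intercept_years: float = 45.0
    slope_years_per_kb: float = 2.5
    sigma_years: float = 5.0
    min_onset_years: float = 10.0
    tremor_mean_years: float = 30.0
    tremor_sd_years: float = 10.0


def _jitter_counts(counts: Sequence[int], cv: float, rng: np.random.Generator) -> list[int]:
    if cv <= 0:
        return [int(c) for c in counts]
    sigma2 = math.log1p(cv * cv)
    mu = -sigma2 / 2.0  # unit-mean log-normal
    factors = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=len(counts))
    return [int(round(c * f)) for c, f in zip(counts, factors)]


def simulate_allele_population(
    model: ExpansionModel, n_cells: int, seed: int
) -> pd.DataFrame:
    """Per-cell truth table for one carrier individual.

    Each cell carries a normal allele (allele 1) and an expanded allele
    (allele 2) with jittered per-segment unit counts, a drawn
    configuration, and a rearrangement indicator with probability
    ``p_rearrange`` of the cell's expansion size. Configuration C1 has no
    3' first-motif part.
    """
    rng = np.random.default_rng(seed)
    labels = sorted(model.config_mix)
    probs = np.array([model.config_mix[l] for l in labels])
    rows = []
    for cell in range(n_cells):
        n5, nmid, n3 = _jitter_counts(model.germline, model.somatic_cv, rng)
        config = labels[int(rng.choice(len(labels), p=probs))]
        if config == "C1":
            n3 = 0
        if nmid == 0:
            config = "C5" if config == "C5" else "NA"
        size_kb = (n5 + nmid + n3) * 5 / 1000.0
        rearranged = bool(rng.random() < model.p_rearrange(size_kb))
        rows.append({
            "cell_id": f"cell{cell:05d}", "allele": 1,
            "n_5p": model.normal_units, "n_mid": 0, "n_3p": 0,
            "size_kb": model.normal_units * 5 / 1000.0,
            "configuration": "NA", "rearranged": False,
        })
        rows.append({
            "cell_id": f"cell{cell:05d}", "allele": 2,
            "n_5p": n5, "n_mid": nmid, "n_3p": n3,
            "size_kb": size_kb, "configuration": config,
            "rearranged": rearranged,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sequence emitters
# ---------------------------------------------------------------------------

def allele_sequence(n5: int, nmid: int, n3: int, config: LocusConfig) -> str:
    m5, mmid = config.motifs[0], config.motifs[1]
    return config.left_flank + m5 * n5 + mmid * nmid + m5 * n3 + config.right_flank


def apply_errors(seq: str, error_model: ReadErrorModel, rng: np.random.Generator) -> str:
    """Apply per-base substitution/insertion/deletion errors."""
    if error_model.total == 0:
        return seq
    out: list[str] = []
    n = len(seq)
    subs = rng.random(n)
    dels = rng.random(n)
    ins = rng.random(n)
    for i, base in enumerate(seq):
        if dels[i] < error_model.deletion:
            continue
        if subs[i] < error_model.substitution:
            choices = [b for b in "ACGT" if b != base]
            base = choices[int(rng.integers(3))]
        out.append(base)
        if ins[i] < error_model.insertion:
            out.append("ACGT"[int(rng.integers(4))])
    return "".join(out)


def emit_long_reads(
    cells: pd.DataFrame,
    config: LocusConfig,
    error_model: ReadErrorModel,
    n_reads: int,
    seed: int,
    p_truncate: float = 0.0,
    p_translocate: float = 0.0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Emit locus-spanning long reads sampled from expanded alleles.

    Reads are emitted on random strands; with probability ``p_truncate`` a
    read is cut inside the repeat (losing the right flank) to create
    partial coverage, and with probability ``p_translocate`` its 3' side is
    replaced by foreign sequence (no right anchor), mimicking a fused
    rearrangement read. Returns (id, sequence) pairs plus a truth table.
    """
    rng = np.random.default_rng(seed)
    expanded = cells[cells["allele"] == 2].reset_index(drop=True)
    if expanded.empty:
        raise ValueError("no expanded alleles in the truth table")
    reads: list[tuple[str, str]] = []
    truth_rows = []
    for i in range(n_reads):
        cell = expanded.iloc[int(rng.integers(len(expanded)))]
        n5, nmid, n3 = int(cell.n_5p), int(cell.n_mid), int(cell.n_3p)
        seq = allele_sequence(n5, nmid, n3, config)
        kind = "full"
        if rng.random() < p_translocate:
            kind = "translocated"
            cut = len(config.left_flank) + 5 * (n5 + nmid // 2)
            foreign = "".join(BASES[rng.integers(4, size=2000)])
            seq = seq[:cut] + foreign
        elif rng.random() < p_truncate:
            kind = "left_partial"
            repeat_len = 5 * (n5 + nmid + n3)
            cut = len(config.left_flank) + int(rng.integers(repeat_len // 2, repeat_len))
            seq = seq[:cut]
        seq = apply_errors(seq, error_model, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = reverse_complement(seq)
        read_id = f"read{i:05d}"
        reads.append((read_id, seq))
        truth_rows.append({
            "read_id": read_id, "cell_id": cell.cell_id, "strand": strand,
            "kind": kind, "n_5p": n5, "n_mid": nmid, "n_3p": n3,
            "total_units": n5 + nmid + n3,
            "size_kb": (n5 + nmid + n3) * 5 / 1000.0,
        })
    return reads, pd.DataFrame(truth_rows)


def emit_short_reads(
    cells: pd.DataFrame,
    config: LocusConfig,
    coverage: float,
    seed: int,
    read_length: int = 150,
    fragment_length: int = 400,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Emit paired 150-bp reads by uniform fragment sampling over the locus.

    Fragments are drawn uniformly over each sampled allele's flank +
    repeat + flank sequence; R1 is the fragment start, R2 the reverse
    complement of the fragment end. Returns (R1, R2) lists of (id, seq).
    """
    rng = np.random.default_rng(seed)
    if coverage <= 0:
        return [], []
    alleles = cells.reset_index(drop=True)
    seqs = [allele_sequence(int(r.n_5p), int(r.n_mid), int(r.n_3p), config)
            for r in alleles.itertuples(index=False)]
    mean_len = float(np.mean([len(s) for s in seqs]))
    n_frags = max(1, int(round(coverage * mean_len / (2 * read_length))))
    r1: list[tuple[str, str]] = []
    r2: list[tuple[str, str]] = []
    for i in range(n_frags):
        j = int(rng.integers(len(seqs)))
        seq = seqs[j]
        flen = min(fragment_length, len(seq))
        start = int(rng.integers(0, len(seq) - flen + 1))
        frag = seq[start:start + flen]
        rid = f"frag{i:06d}"
        r1.append((rid + "/1", frag[:read_length]))
        r2.append((rid + "/2", reverse_complement(frag[-read_length:])))
    return r1, r2


# ---------------------------------------------------------------------------
# Combing emitter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeMap:
    """Fixed probe signal lengths and the unstained baseline, in kb."""

    b_kb: float = 10.0
    g_kb: float = 10.0
    y_base_kb: float = 2.5


def _expanded_tokens(
    n5: int, nmid: int, n3: int, config_label: str, probe: ProbeMap
) -> tuple[list[str], list[float]]:
    kb5 = n5 * 5 / 1000.0
    kbm = nmid * 5 / 1000.0
    kb3 = n3 * 5 / 1000.0
    y = probe.y_base_kb + kb5
    if config_label == "C1":
        toks, kbs = ["B", "Y", "R", "G"], [probe.b_kb, y, kbm, probe.g_kb]
    elif config_label == "C2":
        toks, kbs = ["B", "Y", "R", "W", "G"], [probe.b_kb, y, kbm, kb3, probe.g_kb]
    elif config_label == "C3":
        toks = ["B", "Y", "R", "W", "R", "G"]
        kbs = [probe.b_kb, y, kbm / 2, kb3, kbm / 2, probe.g_kb]
    elif config_label == "C4":
        toks = ["B", "Y", "R", "W", "R", "W", "G"]
        kbs = [probe.b_kb, y, kbm / 2, kb3 / 2, kbm / 2, kb3 / 2, probe.g_kb]
    elif config_label == "C5":
        toks = ["B", "Y", "G"]
        kbs = [probe.b_kb, probe.y_base_kb + kb5 + kbm + kb3, probe.g_kb]
    else:  # C6: three red segments
        toks = ["B", "Y", "R", "W", "R", "W", "R", "G"]
        kbs = [probe.b_kb, y, kbm / 3, kb3 / 2, kbm / 3, kb3 / 2, kbm / 3, probe.g_kb]
    return toks, kbs


_REARRANGED_PATTERNS = (
    (["B", "M", "G"], "overlay"),
    (["B", "Y", "C", "G"], "overlay"),
    (["B", "Y", "R", "R", "B", "G"], "duplicated_flank"),
    (["B", "Y", "R"], "missing_flank"),
    (["G", "W", "R", "Y", "B"], "flank_polarity"),
)


def emit_combing_table(
    cells: pd.DataFrame,
    seed: int,
    probe: ProbeMap = ProbeMap(),
    noise_sd_kb: float = 0.3,
    min_detectable_kb: float = 0.8,
    p_truncate: float = 0.0,
) -> pd.DataFrame:
    """Convert simulated cells into a combing measurement table.

    One fiber per allele. Flank probes get fixed lengths from the probe
    map; Y/R/W lengths derive from the repeat parts. Gaussian noise is
    added per signal, sub-detection signals are dropped, a fraction of
    fibers is truncated, and rearranged alleles emit grammar-violating
    token patterns. Columns match :func:`famex.combing.read_measurements`.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rec in cells.itertuples(index=False):
        fiber_id = f"{rec.cell_id}_a{rec.allele}"
        if rec.rearranged:
            toks, _ = _REARRANGED_PATTERNS[int(rng.integers(len(_REARRANGED_PATTERNS)))]
            toks = list(toks)
            kbs = [probe.b_kb if t in ("B", "M", "C") else
                   probe.g_kb if t == "G" else
                   max(0.5, rng.normal(3.0, 1.0)) for t in toks]
        elif rec.allele == 1 or rec.n_mid == 0:
            y = probe.y_base_kb + (rec.n_5p + rec.n_mid + rec.n_3p) * 5 / 1000.0
            toks, kbs = ["B", "Y", "G"], [probe.b_kb, y, probe.g_kb]
        else:
            toks, kbs = _expanded_tokens(int(rec.n_5p), int(rec.n_mid),
                                         int(rec.n_3p), rec.configuration, probe)
        if noise_sd_kb > 0:
            kbs = [max(0.01, k + rng.normal(0.0, noise_sd_kb)) for k in kbs]
        # rearranged patterns are defined by probe topology: dropping a
        # sub-detection signal must not silently repair the violation
        kept = [(t, k) for t, k in zip(toks, kbs)
                if rec.rearranged or t in ("B", "G", "M", "C")
                or k >= min_detectable_kb]
        if not kept:
            continue
        toks = [t for t, _ in kept]
        kbs = [k for _, k in kept]
        complete = True
        if p_truncate > 0 and rng.random() < p_truncate and len(toks) > 1:
            cut = int(rng.integers(1, len(toks)))
            toks = toks[:cut] + ["END_TRUNCATED"]
            kbs = kbs[:cut] + [0.0]
            complete = False
        rows.append({
            "individual_id": getattr(rec, "individual_id", "sim"),
            "fiber_id": fiber_id,
            "tokens": ",".join(toks),
            "lengths_kb": ",".join(f"{k:.3f}" for k in kbs),
            "complete": int(complete),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort emitter
# ---------------------------------------------------------------------------

def emit_cohort(
    n_individuals: int,
    seed: int,
    phenotype_model: PhenotypeModel = PhenotypeModel(),
    n_cells: int = 100,
    somatic_cv: float = 0.25,
) -> pd.DataFrame:
    """Simulate a cohort: per-individual mean expansion parts plus onsets.

    Germline unit counts are drawn per individual across a paper-scale
    range (total roughly 600-2800 units); per-assay means come from the
    simulated cell population and seizure onset follows the phenotype
    model (inverse in the middle-motif kb), tremor onset independent.
    """
    rng = np.random.default_rng(seed)
    pm = phenotype_model
    rows = []
    for i in range(n_individuals):
        germline = (int(rng.integers(300, 700)),
                    int(rng.integers(100, 1800)),
                    int(rng.integers(30, 300)))
        model = ExpansionModel(germline=germline, somatic_cv=somatic_cv)
        cells = simulate_allele_population(model, n_cells,
                                           seed=int(rng.integers(2**31)))
        exp = cells[cells["allele"] == 2]
        kb5 = float(exp["n_5p"].mean() * 5 / 1000.0)
        kbm = float(exp["n_mid"].mean() * 5 / 1000.0)
        kb3 = float(exp["n_3p"].mean() * 5 / 1000.0)
        seizure = pm.intercept_years - pm.slope_years_per_kb * kbm
        if pm.sigma_years > 0:
            seizure += rng.normal(0.0, pm.sigma_years)
        seizure = max(pm.min_onset_years, seizure)
        tremor = max(pm.min_onset_years,
                     rng.normal(pm.tremor_mean_years, pm.tremor_sd_years))
        rows.append({
            "individual_id": f"sim-{i:03d}",
            "family_id": "simfam",
            "sex": "F" if rng.random() < 0.5 else "M",
            "age_last_exam": round(max(seizure, tremor) + 20, 1),
            "age_tremor_onset": round(tremor, 1),
            "age_seizure_onset": round(seizure, 1),
            "combing_blood_n_p": len(exp),
            "combing_blood_total_kb": round(kb5 + kbm + kb3, 3),
            "combing_blood_5p_kb": round(kb5, 3),
            "combing_blood_mid_kb": round(kbm, 3),
            "combing_blood_3p_kb": round(kb3, 3),
        })
    return pd.DataFrame(rows)
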