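"""Genotype-phenotype correlation and qPCR relative-expression statistics."""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (too few pairs, zero variance)."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r2: float
    ci_low: float
    ci_high: float
    n: int


def pearson_with_ci(
    x: Sequence[float], y: Sequence[float], confidence: float = 0.95
) -> CorrelationResult:
    """Pearson correlation with a Fisher-z confidence interval.

    Pairs with a missing value on either side are dropped; at least three
    complete pairs and non-zero variance on both sides are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise UndefinedCorrelationError(f"need >= 3 complete pairs, got {n}")
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        raise UndefinedCorrelationError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if n == 3 or abs(r) == 1.0:
        ci_low, ci_high = (-1.0, 1.0) if n == 3 else (r, r)
    else:
        z = math.atanh(r)
        zcrit = stats.norm.ppf(0.5 + confidence / 2)
        half = zcrit / math.sqrt(n - 3)
        ci_low, ci_high = math.tanh(z - half), math.tanh(z + half)
    return CorrelationResult(r=r, r2=r * r, ci_low=ci_low, ci_high=ci_high, n=n)


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

PHENOTYPES = ("age_seizure_onset", "age_tremor_onset")
PART_COLUMNS = {
    "total": "total_kb",
    "5p": "5p_kb",
    "mid": "mid_kb",
    "5p_plus_3p": None,  # derived: 5p + 3p
}


def load_cohort(path: str | Path | None = None) -> pd.DataFrame:
    """Load a cohort TSV; defaults to the packaged 10-individual table.

    Censored entries such as ">5" parse to NaN (excluded from statistics);
    NA marks unavailable measurements.
    """
    if path is None:
        source = resources.files("famex.data").joinpath("cohort_table.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    numeric = [c for c in df.columns
               if c not in ("individual_id", "family_id", "sex")]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def onset_correlation_report(
    cohort: pd.DataFrame, assay: str = "combing_blood"
) -> pd.DataFrame:
    """Correlate onset ages against expansion-part means for one assay.

    One row per (phenotype, part) cell over {seizure, tremor} x {total,
    5'-part, middle part, 5'+3' parts}; cells with fewer than three
    complete pairs or zero variance are flagged NA.
    """
    rows = []
    for phenotype in PHENOTYPES:
        for part, suffix in PART_COLUMNS.items():
            if suffix is None:
                values = (cohort[f"{assay}_5p_kb"] + cohort[f"{assay}_3p_kb"])
            else:
                values = cohort[f"{assay}_{suffix}"]
            row = {"phenotype": phenotype, "part": part, "assay": assay}
            try:
                res = pearson_with_ci(cohort[phenotype].to_numpy(dtype=float),
                                      values.to_numpy(dtype=float))
                row.update(r=res.r, r2=res.r2, ci_low=res.ci_low,
                           ci_high=res.ci_high, n=res.n, status="ok")
            except UndefinedCorrelationError as exc:
                row.update(r=float("nan"), r2=float("nan"),
                           ci_low=float("nan"), ci_high=float("nan"),
                           n=0, status=f"NA: {exc}")
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR relative expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionComparison:
    abundances: pd.DataFrame  # sample_id, group, delta_ct, rel_abundance
    p_value: float
    n_carriers: int
    n_controls: int


def relative_expression_ddct(
    ct: pd.DataFrame, control_ids: Iterable[str]
) -> ExpressionComparison:
    """Delta-delta-Ct relative abundance and carrier/control comparison.

    For each sample, delta Ct = Ct_target - Ct_reference; delta-delta Ct
    subtracts the mean delta Ct of the controls, and relative abundance is
    2**(-ddCt). Groups are compared with a two-sided exact
    Wilcoxon-Mann-Whitney rank-sum test. Samples missing either Ct are
    dropped with a warning column rather than an exception.
    """
    required = {"sample_id", "ct_target", "ct_reference"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    control_ids = set(control_ids)
    if len(control_ids) < 2:
        raise ValueError("need at least two control samples")
    df = ct.copy()
    df["ct_target"] = pd.to_numeric(df["ct_target"], errors="coerce")
    df["ct_reference"] = pd.to_numeric(df["ct_reference"], errors="coerce")
    df["dropped"] = df["ct_target"].isna() | df["ct_reference"].isna()
    ok = df[~df["dropped"]].copy()
    ok["group"] = np.where(ok["sample_id"].isin(control_ids), "control", "carrier")
    ok["delta_ct"] = ok["ct_target"] - ok["ct_reference"]
    control_mean = ok.loc[ok["group"] == "control", "delta_ct"].mean()
    if np.isnan(control_mean):
        raise ValueError("no control samples with complete Ct values")
    ok["ddct"] = ok["delta_ct"] - control_mean
    ok["rel_abundance"] = 2.0 ** (-ok["ddct"])
    carriers = ok.loc[ok["group"] == "carrier", "rel_abundance"].to_numpy()
    controls = ok.loc[ok["group"] == "control", "rel_abundance"].to_numpy()
    if len(carriers) and len(controls):
        method = "exact" if (len(np.unique(np.concatenate([carriers, controls])))
                             == len(carriers) + len(controls)) else "auto"
        p = float(stats.mannwhitneyu(carriers, controls, alternative="two-sided",
                                     method=method).pvalue)
    else:
        p = float("nan")
    return ExpressionComparison(
        abundances=ok[["sample_id", "group", "delta_ct", "ddct", "rel_abundance"]],
        p_value=p, n_carriers=len(carriers), n_controls=len(controls))
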