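"""Molecular-combing (fiber-FISH) measurement analysis.

Each stretched fiber yields a token sequence over {B, Y, R, W, G, M, C}
with a measured length in kb per token: B and G are the 5' and 3' flank
probes, R the repeat probe, Y the unstained stretch between B and the
first R (or between B and G when no R is present), W unstained stretches
between R and G or between two R signals, and M/C overlay artifacts.
Alleles are classified, sized against a per-individual baseline, assigned
a configuration, and summarized per individual.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TOKENS = ("B", "Y", "R", "W", "G", "M", "C", "END_TRUNCATED")

NORMAL_MAX_KB = 5.5
PATHOGENIC_MIN_KB = 8.5


class MeasurementError(ValueError):
    """A required signal length is missing from a fiber."""


class BaselineUnavailableError(ValueError):
    """An individual has no normal alleles to compute the Y baseline from."""


@dataclass(frozen=True)
class CombingAllele:
    """One fiber's signal token sequence with per-token lengths in kb."""

    individual_id: str
    fiber_id: str
    tokens: tuple[str, ...]
    lengths_kb: tuple[float, ...]
    complete: bool = True

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.lengths_kb):
            raise MeasurementError(
                f"fiber {self.fiber_id}: {len(self.tokens)} tokens but "
                f"{len(self.lengths_kb)} lengths"
            )
        for t in self.tokens:
            if t not in TOKENS:
                raise MeasurementError(f"fiber {self.fiber_id}: unknown token {t!r}")
        if any(l < 0 for l in self.lengths_kb):
            raise MeasurementError(f"fiber {self.fiber_id}: negative length")
        truncated = "END_TRUNCATED" in self.tokens
        if truncated == self.complete:
            raise MeasurementError(
                f"fiber {self.fiber_id}: complete flag inconsistent with tokens"
            )

    def total(self, token: str) -> float:
        return float(sum(l for t, l in zip(self.tokens, self.lengths_kb) if t == token))

    def has(self, token: str) -> bool:
        return token in self.tokens


def flag_rearrangement(tokens: Sequence[str]) -> tuple[bool, str | None]:
    """Detect grammar-violating (micro-rearranged) token patterns.

    Rules, first match recorded as reason: probe overlay (M or C); a
    missing flank while the other flank and R are present; a duplicated
    flank; flank polarity violation (G before B).
    """
    toks = [t for t in tokens if t != "END_TRUNCATED"]
    if "M" in toks or "C" in toks:
        return True, "overlay"
    has_b, has_g, has_r = "B" in toks, "G" in toks, "R" in toks
    if has_r and (has_b != has_g):
        return True, "missing_flank"
    if toks.count("B") > 1 or toks.count("G") > 1:
        return True, "duplicated_flank"
    if has_b and has_g and toks.index("G") < toks.index("B"):
        return True, "flank_polarity"
    return False, None


def classify_allele(
    allele: CombingAllele,
    normal_max_kb: float = NORMAL_MAX_KB,
    pathogenic_min_kb: float = PATHOGENIC_MIN_KB,
) -> str:
    """Classify a complete, non-rearranged allele.

    Red-positive alleles are definite pathogenic. Red-negative alleles are
    classified on the unstained length Y: normal below ``normal_max_kb``,
    likely pathogenic at or above ``pathogenic_min_kb``, undefined in
    between (boundary values 5.5 -> U, 8.5 -> P).
    """
    if not allele.complete:
        raise ValueError("classify_allele requires a complete allele")
    rearranged, _ = flag_rearrangement(allele.tokens)
    if rearranged:
        raise ValueError("classify_allele requires a non-rearranged allele")
    if allele.has("R"):
        return "P_definite"
    if not allele.has("Y"):
        raise MeasurementError(
            f"fiber {allele.fiber_id}: red-negative allele without Y measurement"
        )
    y = allele.total("Y")
    if y < normal_max_kb:
        return "N"
    if y < pathogenic_min_kb:
        return "U"
    return "P_likely"


def expansion_size(yp_kb: float, yn_kb: float, r_total_kb: float, w_total_kb: float) -> float:
    """Total expansion size: Yp - Yn + R + W (may be slightly negative)."""
    return yp_kb - yn_kb + r_total_kb + w_total_kb


def assign_configuration(
    tokens: Sequence[str],
    y_kb: float | None = None,
    pathogenic_min_kb: float = PATHOGENIC_MIN_KB,
) -> str:
    """Map an accepted token pattern to a configuration label C1-C6.

    The taxonomy is a declared convention: C1 [B,Y,R,G]; C2 [B,Y,R,W,G];
    C3 [B,Y,R,W,R,G]; C4 [B,Y,R,W,R,W,G]; C5 [B,Y,G] with an expanded Y
    (red-negative likely pathogenic); C6 any other accepted pattern with
    at least three R segments. Everything else is NA.
    """
    toks = tuple(t for t in tokens if t != "END_TRUNCATED")
    rearranged, _ = flag_rearrangement(toks)
    if rearranged:
        raise ValueError("assign_configuration requires a non-rearranged pattern")
    mapping = {
        ("B", "Y", "R", "G"): "C1",
        ("B", "Y", "R", "W", "G"): "C2",
        ("B", "Y", "R", "W", "R", "G"): "C3",
        ("B", "Y", "R", "W", "R", "W", "G"): "C4",
    }
    if toks in mapping:
        return mapping[toks]
    if toks == ("B", "Y", "G"):
        if y_kb is not None and y_kb >= pathogenic_min_kb:
            return "C5"
        return "NA"
    # accepted free-form pattern: B ... G with interleaved Y/R/W
    if (len(toks) >= 2 and toks[0] == "B" and toks[-1] == "G"
            and all(t in ("Y", "R", "W") for t in toks[1:-1])
            and toks.count("R") >= 3):
        return "C6"
    return "NA"


@dataclass(frozen=True)
class AlleleCall:
    """Classification and sizing of one fiber."""

    individual_id: str
    fiber_id: str
    allele_class: str  # N | U | P_likely | P_definite | rearranged | incomplete
    reason: str | None
    y_kb: float | None
    r_total_kb: float
    w_total_kb: float
    expansion_kb: float | None
    part_5p_kb: float | None  # Yp - Yn
    part_mid_kb: float | None  # sum of R
    part_3p_kb: float | None  # sum of W
    configuration: str
    negative_size: bool = False

    @property
    def is_pathogenic(self) -> bool:
        return self.allele_class in ("P_definite", "P_likely")


@dataclass(frozen=True)
class IndividualBaseline:
    individual_id: str
    yn_kb: float
    n_normal_alleles: int


def individual_baseline(
    individual_id: str, classes: Sequence[str], alleles: Sequence[CombingAllele]
) -> IndividualBaseline:
    ys = [a.total("Y") for a, c in zip(alleles, classes) if c == "N"]
    if not ys:
        raise BaselineUnavailableError(
            f"individual {individual_id}: no normal alleles for Y baseline"
        )
    return IndividualBaseline(individual_id=individual_id,
                              yn_kb=float(np.median(ys)),
                              n_normal_alleles=len(ys))


def call_individual(
    alleles: Sequence[CombingAllele],
    normal_max_kb: float = NORMAL_MAX_KB,
    pathogenic_min_kb: float = PATHOGENIC_MIN_KB,
) -> tuple[list[AlleleCall], IndividualBaseline]:
    """Classify and size all fibers of one individual.

    First pass assigns classes (incomplete and rearranged take precedence);
    the Y baseline Yn is the median Y of the individual's N alleles; the
    second pass sizes pathogenic alleles as Yp - Yn + R + W, with the
    three-part split (Yp - Yn, sum R, sum W).
    """
    if not alleles:
        return [], None  # type: ignore[return-value]
    individual_id = alleles[0].individual_id
    classes: list[str] = []
    reasons: list[str | None] = []
    for a in alleles:
        if not a.complete:
            classes.append("incomplete")
            reasons.append("truncated_fiber")
            continue
        rearranged, why = flag_rearrangement(a.tokens)
        if rearranged:
            classes.append("rearranged")
            reasons.append(why)
            continue
        classes.append(classify_allele(a, normal_max_kb, pathogenic_min_kb))
        reasons.append(None)

    baseline = individual_baseline(individual_id, classes, alleles)

    calls: list[AlleleCall] = []
    for a, cls, why in zip(alleles, classes, reasons):
        y = a.total("Y") if a.has("Y") else None
        r_total, w_total = a.total("R"), a.total("W")
        if cls in ("P_definite", "P_likely"):
            if y is None:
                raise MeasurementError(
                    f"fiber {a.fiber_id}: pathogenic allele without Y measurement"
                )
            size = expansion_size(y, baseline.yn_kb, r_total, w_total)
            part5 = y - baseline.yn_kb
            config = assign_configuration(a.tokens, y_kb=y,
                                          pathogenic_min_kb=pathogenic_min_kb)
            calls.append(AlleleCall(
                individual_id=a.individual_id, fiber_id=a.fiber_id,
                allele_class=cls, reason=why, y_kb=y,
                r_total_kb=r_total, w_total_kb=w_total,
                expansion_kb=size, part_5p_kb=part5, part_mid_kb=r_total,
                part_3p_kb=w_total, configuration=config,
                negative_size=size < 0))
        else:
            calls.append(AlleleCall(
                individual_id=a.individual_id, fiber_id=a.fiber_id,
                allele_class=cls, reason=why, y_kb=y,
                r_total_kb=r_total, w_total_kb=w_total,
                expansion_kb=None, part_5p_kb=None, part_mid_kb=None,
                part_3p_kb=None, configuration="NA"))
    return calls, baseline


def cohort_summary(
    alleles_by_individual: Mapping[str, Sequence[CombingAllele]],
    normal_max_kb: float = NORMAL_MAX_KB,
    pathogenic_min_kb: float = PATHOGENIC_MIN_KB,
) -> pd.DataFrame:
    """Per-individual summary table.

    Size statistics (mean, median, SD of the expansion and its parts) are
    computed over pathogenic alleles only; rearranged and incomplete
    alleles are excluded from all size statistics. The rearrangement rate
    per allele is converted to a per-cell percentage assuming at most one
    rearranged allele per cell (factor 2, capped at 100%).
    """
    rows = []
    for ind, alleles in alleles_by_individual.items():
        calls, baseline = call_individual(list(alleles), normal_max_kb,
                                          pathogenic_min_kb)
        n_total = len(calls)
        n_incomplete = sum(c.allele_class == "incomplete" for c in calls)
        n_complete = n_total - n_incomplete
        n_rearranged = sum(c.allele_class == "rearranged" for c in calls)
        p_calls = [c for c in calls if c.is_pathogenic]
        pct_alleles = 100.0 * n_rearranged / n_complete if n_complete else float("nan")
        pct_cells = min(100.0, 2.0 * pct_alleles) if n_complete else float("nan")

        def stats(values: list[float]) -> tuple[float, float, float]:
            if not values:
                return float("nan"), float("nan"), float("nan")
            arr = np.asarray(values, dtype=float)
            sd = float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
            return float(arr.mean()), float(np.median(arr)), sd

        row = {
            "individual_id": ind,
            "n_alleles": n_total,
            "n_complete": n_complete,
            "n_N": sum(c.allele_class == "N" for c in calls),
            "n_U": sum(c.allele_class == "U" for c in calls),
            "n_P": len(p_calls),
            "n_rearranged": n_rearranged,
            "n_incomplete": n_incomplete,
            "yn_kb": baseline.yn_kb,
            "percent_rearranged_alleles": pct_alleles,
            "percent_rearranged_cells": pct_cells,
        }
        for label, getter in (
            ("expansion_kb", lambda c: c.expansion_kb),
            ("part_5p_kb", lambda c: c.part_5p_kb),
            ("part_mid_kb", lambda c: c.part_mid_kb),
            ("part_3p_kb", lambda c: c.part_3p_kb),
        ):
            mean, median, sd = stats([getter(c) for c in p_calls])
            row[f"mean_{label}"] = mean
            row[f"median_{label}"] = median
            row[f"sd_{label}"] = sd
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------

def read_measurements(path: str | Path) -> dict[str, list[CombingAllele]]:
    """Load a combing measurement TSV into alleles grouped by individual.

    Columns: individual_id, fiber_id, tokens (comma-joined), lengths_kb
    (comma-joined, one value per token), complete (0/1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual_id", "fiber_id", "tokens", "lengths_kb", "complete"}
    missing = required - set(df.columns)
    if missing:
        raise MeasurementError(f"measurement table missing columns: {sorted(missing)}")
    out: dict[str, list[CombingAllele]] = {}
    for rec in df.itertuples(index=False):
        allele = CombingAllele(
            individual_id=rec.individual_id,
            fiber_id=rec.fiber_id,
            tokens=tuple(rec.tokens.split(",")),
            lengths_kb=tuple(float(x) for x in rec.lengths_kb.split(",")),
            complete=rec.complete in ("1", "True", "true"),
        )
        out.setdefault(allele.individual_id, []).append(allele)
    return out


def write_measurements(alleles: Iterable[CombingAllele], path: str | Path) -> None:
    rows = [{
        "individual_id": a.individual_id,
        "fiber_id": a.fiber_id,
        "tokens": ",".join(a.tokens),
        "lengths_kb": ",".join(f"{l:.3f}" for l in a.lengths_kb),
        "complete": int(a.complete),
    } for a in alleles]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def allele_calls_frame(calls: Iterable[AlleleCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "individual_id": c.individual_id,
        "fiber_id": c.fiber_id,
        "allele_class": c.allele_class,
        "reason": c.reason or "",
        "configuration": c.configuration,
        "y_kb": c.y_kb,
        "r_total_kb": c.r_total_kb,
        "w_total_kb": c.w_total_kb,
        "expansion_kb": c.expansion_kb,
        "part_5p_kb": c.part_5p_kb,
        "part_mid_kb": c.part_mid_kb,
        "part_3p_kb": c.part_3p_kb,
        "negative_size": int(c.negative_size),
    } for c in calls])
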