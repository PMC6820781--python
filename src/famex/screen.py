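"""Short-read expansion screening at a configured repeat locus.

A deliberately transparent detector: reads are classified by exact flank
anchoring and exact canonical-motif tiling, then spanning-read unit counts
are clustered into at most two alleles. In-repeat reads turn one allele
into a lower bound and drive the expansion call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .decompose import decompose
from .locus import LocusConfig
from .sequence import canonical_motif, reverse_complement


@dataclass(frozen=True)
class ReadClass:
    category: str  # spanning | anchored_in_repeat | fully_in_repeat | irrelevant
    unit_counts: dict[str, int] | None = None  # per motif, spanning reads only
    motif: str | None = None  # canonical motif for in-repeat categories


@dataclass(frozen=True)
class AlleleEstimate:
    unit_counts: dict[str, int]
    lower_bound: bool
    n_reads: int

    @property
    def total_units(self) -> int:
        return sum(self.unit_counts.values())


@dataclass(frozen=True)
class ScreenResult:
    locus_id: str
    n_spanning_reads: int
    n_anchored_inrepeat_reads: int
    n_fully_inrepeat_reads: int
    allele_estimates: tuple[AlleleEstimate, ...]
    expansion_call: dict[str, bool]
    no_coverage: bool = False


def _tiling_fraction(seq: str, motif: str) -> float:
    """Fraction of the read covered by exact tandem runs of the motif."""
    if not seq:
        return 0.0
    structure = decompose(seq, [motif], min_units=2, max_merge_gap=0)
    covered = sum(s.span_bases for s in structure.segments)
    return covered / len(seq)


def _count_tandem_at(seq: str, motif: str, from_end: bool) -> int:
    """Number of exact tandem copies at one end of the sequence."""
    k = len(motif)
    n = 0
    if from_end:
        while seq.endswith(motif * (n + 1)):
            n += 1
    else:
        while seq.startswith(motif * (n + 1)):
            n += 1
    return n


def _inner_motif_copies(inner: str, motifs: Sequence[str], anchored_left: bool) -> int:
    """Max tandem copies of any motif at the inner (repeat-facing) end."""
    best = 0
    for m in motifs:
        best = max(best, _count_tandem_at(inner, m, from_end=not anchored_left))
    return best


def classify_read(
    read: str,
    config: LocusConfig,
    min_anchor: int = 20,
    min_inner_units: int = 4,
    inrepeat_fraction: float = 0.9,
) -> ReadClass:
    """Classify one short read with respect to the locus.

    spanning: both flank anchors present; anchored_in_repeat: exactly one
    anchor plus at least ``min_inner_units`` tandem motif copies at the
    inner end; fully_in_repeat: at least ``inrepeat_fraction`` of the read
    tiled by exact copies of one motif (either strand); otherwise
    irrelevant.
    """
    read = read.upper()
    if len(read) < 2 * min_anchor:
        raise ValueError(f"read shorter than 2*min_anchor={2 * min_anchor}")
    left_a = config.left_flank[-min_anchor:]
    right_a = config.right_flank[:min_anchor]

    for oriented in (read, reverse_complement(read)):
        li = oriented.find(left_a)
        ri = oriented.find(right_a)
        if li >= 0 and ri >= 0 and ri >= li + min_anchor:
            inner = oriented[li + min_anchor:ri]
            structure = decompose(inner, config.motifs, min_units=1, max_merge_gap=0)
            counts = {m: structure.units_for(m) for m in config.motifs}
            return ReadClass(category="spanning", unit_counts=counts)
        if li >= 0 or ri >= 0:
            if li >= 0:
                inner = oriented[li + min_anchor:]
                units = _inner_motif_copies(inner, config.motifs, anchored_left=True)
            else:
                inner = oriented[:ri]
                units = _inner_motif_copies(inner, config.motifs, anchored_left=False)
            if units >= min_inner_units:
                best_m = max(config.motifs,
                             key=lambda m: _tiling_fraction(inner, m))
                return ReadClass(category="anchored_in_repeat",
                                 motif=canonical_motif(best_m))

    for m in config.motifs:
        if (_tiling_fraction(read, m) >= inrepeat_fraction
                or _tiling_fraction(reverse_complement(read), m) >= inrepeat_fraction):
            return ReadClass(category="fully_in_repeat", motif=canonical_motif(m))
    return ReadClass(category="irrelevant")


def _cluster_counts(totals: list[int], tolerance: int = 1) -> list[list[int]]:
    """1-D single-linkage clustering of spanning totals at the tolerance."""
    if not totals:
        return []
    totals = sorted(totals)
    clusters = [[totals[0]]]
    for t in totals[1:]:
        if t - clusters[-1][-1] <= tolerance:
            clusters[-1].append(t)
        else:
            clusters.append([t])
    return clusters


def genotype_locus(
    reads: Iterable[str],
    config: LocusConfig,
    min_anchor: int = 20,
    normal_max_units: int = 30,
    read_length: int | None = None,
) -> ScreenResult:
    """Genotype one individual's reads at the locus.

    Spanning reads are clustered by total unit count (tolerance 1) into at
    most two alleles; in-repeat evidence adds a lower-bound allele. The
    expansion call for the second motif (TTTCA-like) is positive on any
    presence; the first motif requires a lower-bound allele or a unit count
    above ``normal_max_units``.
    """
    spanning: list[dict[str, int]] = []
    n_anchored = n_fully = 0
    anchored_motifs: set[str] = set()
    fully_motifs: set[str] = set()
    canon = {canonical_motif(m): m for m in config.motifs}
    for read in reads:
        rc = classify_read(read, config, min_anchor=min_anchor)
        if rc.category == "spanning":
            spanning.append(rc.unit_counts)
        elif rc.category == "anchored_in_repeat":
            n_anchored += 1
            anchored_motifs.add(rc.motif)
        elif rc.category == "fully_in_repeat":
            n_fully += 1
            fully_motifs.add(rc.motif)

    # Lower-bound evidence: the reference motif (motifs[0]) is present on
    # every normal allele, so reads merely ending inside a normal tract
    # must not count; only fully-in-repeat reads (impossible from a
    # normal-length tract) qualify. Any in-repeat evidence qualifies for
    # the non-reference motifs, which are absent from controls.
    ref_canon = canonical_motif(config.motifs[0])
    inrepeat_motifs = fully_motifs | {m for m in anchored_motifs if m != ref_canon}

    if not spanning and n_anchored == 0 and n_fully == 0:
        return ScreenResult(locus_id=config.locus_id, n_spanning_reads=0,
                            n_anchored_inrepeat_reads=0, n_fully_inrepeat_reads=0,
                            allele_estimates=(), expansion_call={m: False for m in config.motifs},
                            no_coverage=True)

    totals = [sum(c.values()) for c in spanning]
    clusters = _cluster_counts(totals)
    clusters.sort(key=len, reverse=True)
    alleles: list[AlleleEstimate] = []
    for cluster in clusters[:2]:
        members = [c for c in spanning if sum(c.values()) in set(cluster)]
        counts = {m: round(sum(c[m] for c in members) / len(members))
                  for m in config.motifs}
        alleles.append(AlleleEstimate(unit_counts=counts, lower_bound=False,
                                      n_reads=len(members)))
    has_lower_bound = bool(inrepeat_motifs)
    if has_lower_bound:
        lb_counts = {m: 0 for m in config.motifs}
        for cm in inrepeat_motifs:
            lb_counts[canon[cm]] = 1  # presence marker; true count unobservable
        alleles = alleles[:1] + [AlleleEstimate(unit_counts=lb_counts,
                                                lower_bound=True,
                                                n_reads=n_anchored + n_fully)]
    expansion_call: dict[str, bool] = {}
    for i, m in enumerate(config.motifs):
        present_lb = any(a.lower_bound and a.unit_counts[m] > 0 for a in alleles)
        if i == 0:
            over = any(not a.lower_bound and a.unit_counts[m] > normal_max_units
                       for a in alleles)
            expansion_call[m] = present_lb or over
        else:
            any_units = any(a.unit_counts[m] > 0 for a in alleles)
            expansion_call[m] = present_lb or any_units
    return ScreenResult(
        locus_id=config.locus_id,
        n_spanning_reads=len(spanning),
        n_anchored_inrepeat_reads=n_anchored,
        n_fully_inrepeat_reads=n_fully,
        allele_estimates=tuple(alleles),
        expansion_call=expansion_call,
    )
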