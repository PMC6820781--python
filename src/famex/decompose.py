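"""Long-read repeat decomposition.

Locates a configured repeat locus in a read via flanking anchors, then
decomposes the enclosed stretch into maximal runs of exact motif copies,
with uncovered stretches reported as gaps (interruptions or base-calling
errors). Genomic coordinates are 1-based inclusive; every interval here is
0-based half-open.
"""

from __future__ import annotations

import heapq
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

from .locus import LocusConfig
from .sequence import reverse_complement


class LocusNotFoundError(ValueError):
    """Neither flank anchor was found in the read at the required identity."""


class ParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Repeat structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatSegment:
    """A run of exact tandem motif copies, possibly spanning small merged gaps.

    ``unit_count`` counts exact copies only; ``span_bases`` is the physical
    span, equal to ``unit_count * len(motif)`` for unmerged runs and larger
    when small gaps were merged into the segment.
    """

    motif: str
    unit_count: int
    start_offset: int
    span_bases: int

    @property
    def end_offset(self) -> int:
        return self.start_offset + self.span_bases


@dataclass(frozen=True)
class Gap:
    start_offset: int
    span_bases: int

    @property
    def end_offset(self) -> int:
        return self.start_offset + self.span_bases


@dataclass(frozen=True)
class RepeatStructure:
    segments: tuple[RepeatSegment, ...]
    gaps: tuple[Gap, ...]
    total_span_bases: int

    @property
    def total_units(self) -> int:
        return sum(s.unit_count for s in self.segments)

    def units_for(self, motif: str) -> int:
        return sum(s.unit_count for s in self.segments if s.motif == motif)

    def structure_string(self) -> str:
        return "".join(f"({s.motif}){s.unit_count}" for s in self.segments)

    @property
    def unit_estimate(self) -> int:
        """Span-based estimate of the true unit count.

        ``total_units`` counts exact copies only and therefore undercounts
        on noisy reads (an error anywhere in a 5-base copy voids it). The
        physical span divided by the unit length is robust to point errors
        (only the insertion/deletion imbalance distorts it) and is the
        estimator used for truth-recovery checks on noisy data.
        """
        if not self.segments:
            return 0
        unit_len = len(self.segments[0].motif)
        return int(round(self.total_span_bases / unit_len))


def _candidate_runs(seq: str, motif: str, min_units: int) -> list[tuple[int, int]]:
    """All maximal tandem runs of ``motif`` in ``seq`` as (start, n_units).

    Occurrences are chained at exact motif-length spacing; runs from
    different phases may overlap in bases and are resolved later.
    """
    k = len(motif)
    starts = [m.start() for m in re.finditer(f"(?={re.escape(motif)})", seq)]
    runs: list[tuple[int, int]] = []
    taken: set[int] = set()
    start_set = set(starts)
    for s in starts:
        if s in taken:
            continue
        n = 1
        while s + n * k in start_set:
            taken.add(s + n * k)
            n += 1
        if n >= min_units:
            runs.append((s, n))
    return runs


def decompose(
    seq: str,
    motifs: Sequence[str],
    min_units: int = 2,
    max_merge_gap: int = 10,
) -> RepeatStructure:
    """Decompose a sequence into exact motif runs and gaps.

    Maximal runs of at least ``min_units`` exact tandem copies of each motif
    are found; overlapping candidates (the motifs share prefixes) are
    resolved longest-first with leftmost tie-breaking. Adjacent accepted
    runs of the same motif separated by at most ``max_merge_gap`` bases are
    merged into a single segment whose ``unit_count`` sums exact copies
    only. Everything not covered by a segment is a gap; segments and gaps
    tile ``[0, len(seq))``.
    """
    seq = seq.upper()
    if not seq:
        return RepeatStructure(segments=(), gaps=(), total_span_bases=0)
    if min_units < 1:
        raise ParameterError("min_units must be >= 1")

    unit_lens = {m: len(m) for m in motifs}
    # candidate heap entries: (-span, start, motif, n_units)
    heap: list[tuple[int, int, str, int]] = []
    for m in motifs:
        k = unit_lens[m]
        for start, n in _candidate_runs(seq, m, min_units):
            heapq.heappush(heap, (-n * k, start, m, n))

    accepted: list[tuple[int, int, str, int]] = []  # (start, end, motif, n)
    occupied: list[tuple[int, int]] = []  # sorted accepted intervals

    def free_copies(start: int, n: int, k: int) -> list[tuple[int, int]]:
        """Maximal chains of copies not overlapping any accepted interval."""
        chains: list[tuple[int, int]] = []
        run_start, run_n = None, 0
        for i in range(n):
            a, b = start + i * k, start + (i + 1) * k
            clear = all(b <= lo or a >= hi for lo, hi in occupied)
            if clear:
                if run_start is None:
                    run_start = a
                run_n += 1
            else:
                if run_start is not None:
                    chains.append((run_start, run_n))
                run_start, run_n = None, 0
        if run_start is not None:
            chains.append((run_start, run_n))
        return chains

    while heap:
        negspan, start, m, n = heapq.heappop(heap)
        k = unit_lens[m]
        chains = free_copies(start, n, k)
        if len(chains) == 1 and chains[0] == (start, n):
            accepted.append((start, start + n * k, m, n))
            occupied.append((start, start + n * k))
        else:
            for cs, cn in chains:
                if cn >= min_units:
                    heapq.heappush(heap, (-cn * k, cs, m, cn))

    accepted.sort()

    # merge same-motif neighbours across small gaps
    merged: list[list] = []  # [start, end, motif, n]
    for start, end, m, n in accepted:
        if merged and merged[-1][2] == m and start - merged[-1][1] <= max_merge_gap:
            merged[-1][1] = end
            merged[-1][3] += n
        else:
            merged.append([start, end, m, n])

    segments = tuple(
        RepeatSegment(motif=m, unit_count=n, start_offset=start, span_bases=end - start)
        for start, end, m, n in merged
    )
    gaps = []
    pos = 0
    for s in segments:
        if s.start_offset > pos:
            gaps.append(Gap(start_offset=pos, span_bases=s.start_offset - pos))
        pos = s.end_offset
    if pos < len(seq):
        gaps.append(Gap(start_offset=pos, span_bases=len(seq) - pos))

    return RepeatStructure(segments=segments, gaps=tuple(gaps), total_span_bases=len(seq))


# ---------------------------------------------------------------------------
# Anchoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnchorMatch:
    start: int
    end: int
    identity: float
    score: float


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _make_aligner()


def _best_anchor(query: str, target: str, min_identity: float, min_len: int) -> AnchorMatch | None:
    if len(target) < len(query):
        # still alignable; PairwiseAligner handles it
        pass
    alignments = _ALIGNER.align(target, query)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    aln = alignments[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return None
    identity = counts.identities / columns
    tstart = int(aln.coordinates[0][0])
    tend = int(aln.coordinates[0][-1])
    qcols = int(aln.coordinates[1][-1] - aln.coordinates[1][0])
    if identity < min_identity or qcols < min_len:
        return None
    return AnchorMatch(start=tstart, end=tend, identity=identity, score=float(aln.score))


@dataclass(frozen=True)
class LocusHit:
    orientation: str  # "+" or "-"
    anchor_left: AnchorMatch | None
    anchor_right: AnchorMatch | None
    coverage: str  # full | left_partial | right_partial
    interval: tuple[int, int]  # 0-based half-open, in oriented read


def locate_expansion(
    read: str,
    config: LocusConfig,
    min_identity: float = 0.8,
    min_anchor_len: int = 60,
    anchor_query_len: int = 100,
) -> LocusHit:
    """Find the repeat locus in a read by aligning flank anchors.

    The 3' end of the left flank and the 5' end of the right flank are
    locally aligned against the read and its reverse complement; the
    orientation maximizing summed anchor identity wins. With both anchors
    the enclosed interval is the expansion; a single anchor yields partial
    coverage extending to the read end.
    """
    read = read.upper()
    if len(read) < min_anchor_len:
        raise ParameterError(f"read shorter than min_anchor_len={min_anchor_len}")
    left_q = config.left_flank[-anchor_query_len:]
    right_q = config.right_flank[:anchor_query_len]

    best: LocusHit | None = None
    best_key: tuple = ()
    for orientation in ("+", "-"):
        oriented = read if orientation == "+" else reverse_complement(read)
        left = _best_anchor(left_q, oriented, min_identity, min_anchor_len)
        right = _best_anchor(right_q, oriented, min_identity, min_anchor_len)
        if right is not None and left is not None and right.start < left.end:
            # anchors out of order: keep the stronger one
            if left.identity >= right.identity:
                right = None
            else:
                left = None
        if left is None and right is None:
            continue
        if left and right:
            coverage = "full"
            interval = (left.end, right.start)
        elif left:
            coverage = "left_partial"
            interval = (left.end, len(oriented))
        else:
            coverage = "right_partial"
            interval = (0, right.start)
        total_identity = (left.identity if left else 0.0) + (right.identity if right else 0.0)
        key = (int(left is not None) + int(right is not None), total_identity,
               1 if orientation == "+" else 0)
        if best is None or key > best_key:
            best = LocusHit(orientation=orientation, anchor_left=left,
                            anchor_right=right, coverage=coverage, interval=interval)
            best_key = key
    if best is None:
        raise LocusNotFoundError("no flank anchor found at required identity")
    return best


# ---------------------------------------------------------------------------
# Per-read decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecomposedRead:
    """Anchoring and motif decomposition of one long read."""

    read_id: str
    orientation: str
    coverage: str
    anchor_left: AnchorMatch | None
    anchor_right: AnchorMatch | None
    structure: RepeatStructure
    units_5p: int
    units_mid: int
    units_3p: int
    size_kb_5p: float
    size_kb_mid: float
    size_kb_3p: float
    size_kb_total: float

    @property
    def is_full(self) -> bool:
        return self.coverage == "full"


def _split_motif_classes(
    structure: RepeatStructure, flank_motif: str, mid_motif: str
) -> tuple[int, int, int, float, float, float]:
    """Assign flank-motif segments to 5'/3' around the first mid-motif run.

    Per-motif kb sizes count exact copies only (gap bases excluded); they
    are computed from unit counts at 5 bases per unit.
    """
    first_mid = next(
        (s.start_offset for s in structure.segments if s.motif == mid_motif), None
    )
    u5 = umid = u3 = 0
    for s in structure.segments:
        if s.motif == mid_motif:
            umid += s.unit_count
        elif s.motif == flank_motif:
            if first_mid is None or s.start_offset < first_mid:
                u5 += s.unit_count
            else:
                u3 += s.unit_count
    k = len(flank_motif)
    return u5, umid, u3, u5 * k / 1000.0, umid * len(mid_motif) / 1000.0, u3 * k / 1000.0


def decompose_read(
    read_id: str,
    seq: str,
    config: LocusConfig,
    min_units: int = 2,
    max_merge_gap: int = 10,
    min_identity: float = 0.8,
    min_anchor_len: int = 60,
) -> DecomposedRead:
    """Anchor one read and decompose its expansion interval.

    The total size in kb is the physical span of the expansion interval
    (gaps included); per-motif-class sizes exclude gap bases.
    """
    hit = locate_expansion(seq, config, min_identity=min_identity,
                           min_anchor_len=min_anchor_len)
    oriented = seq.upper() if hit.orientation == "+" else reverse_complement(seq.upper())
    lo, hi = hit.interval
    expansion = oriented[lo:hi] if hi > lo else ""
    structure = decompose(expansion, config.motifs, min_units=min_units,
                          max_merge_gap=max_merge_gap)
    flank_motif, mid_motif = config.motifs[0], config.motifs[1]
    u5, umid, u3, kb5, kbm, kb3 = _split_motif_classes(structure, flank_motif, mid_motif)
    return DecomposedRead(
        read_id=read_id,
        orientation=hit.orientation,
        coverage=hit.coverage,
        anchor_left=hit.anchor_left,
        anchor_right=hit.anchor_right,
        structure=structure,
        units_5p=u5, units_mid=umid, units_3p=u3,
        size_kb_5p=kb5, size_kb_mid=kbm, size_kb_3p=kb3,
        size_kb_total=structure.total_span_bases / 1000.0,
    )


# ---------------------------------------------------------------------------
# Dot plots and summaries
# ---------------------------------------------------------------------------

def dotplot(seq_a: str, seq_b: str, word: int = 10, step: int = 1) -> np.ndarray:
    """Boolean word-match matrix between two sequences.

    Cell (i, j) is True iff the ``word``-length substrings at position
    ``i*step`` of ``seq_a`` and ``j*step`` of ``seq_b`` are identical.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if word < 1 or step < 1:
        raise ParameterError("word and step must be >= 1")
    if word > len(seq_a) or word > len(seq_b):
        raise ParameterError("word longer than a sequence")
    pos_a = range(0, len(seq_a) - word + 1, step)
    pos_b = range(0, len(seq_b) - word + 1, step)
    index: dict[str, list[int]] = {}
    for j, p in enumerate(pos_b):
        index.setdefault(seq_b[p:p + word], []).append(j)
    mat = np.zeros((len(pos_a), len(pos_b)), dtype=bool)
    for i, p in enumerate(pos_a):
        for j in index.get(seq_a[p:p + word], ()):
            mat[i, j] = True
    return mat


@dataclass(frozen=True)
class ReadSetSummary:
    """Per-individual summary over decomposed long reads."""

    n_reads: int
    n_used: int
    mean_size_kb: float | None
    mean_size_kb_5p: float | None
    mean_size_kb_mid: float | None
    mean_size_kb_3p: float | None
    total_units_min: int | None
    total_units_max: int | None

    @property
    def defined(self) -> bool:
        return self.n_used > 0


def summarize_reads(
    reads: Iterable[DecomposedRead], include_partial: bool = False
) -> ReadSetSummary:
    """Summarize a set of decomposed reads from one individual.

    Partial-coverage reads are excluded from the means by default.
    """
    reads = list(reads)
    used = [r for r in reads if include_partial or r.is_full]
    if not used:
        return ReadSetSummary(n_reads=len(reads), n_used=0, mean_size_kb=None,
                              mean_size_kb_5p=None, mean_size_kb_mid=None,
                              mean_size_kb_3p=None, total_units_min=None,
                              total_units_max=None)
    units = [r.structure.total_units for r in used]
    return ReadSetSummary(
        n_reads=len(reads),
        n_used=len(used),
        mean_size_kb=float(np.mean([r.size_kb_total for r in used])),
        mean_size_kb_5p=float(np.mean([r.size_kb_5p for r in used])),
        mean_size_kb_mid=float(np.mean([r.size_kb_mid for r in used])),
        mean_size_kb_3p=float(np.mean([r.size_kb_3p for r in used])),
        total_units_min=min(units),
        total_units_max=max(units),
    )
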