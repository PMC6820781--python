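"""Locus configuration: flanking anchors, motif set, reference tract, thresholds.

Genomic reference coordinates are 1-based inclusive; all internal sequence
intervals elsewhere in the package are 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

VALID_BASES = frozenset("ACGT")


class LocusConfigError(ValueError):
    """Raised when a locus configuration violates its invariants."""


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds for combing alleles, in kb.

    ``normal_max_kb`` is the exclusive upper bound of the normal class;
    ``pathogenic_min_kb`` is the inclusive lower bound of the likely
    pathogenic class. Values in between are "undefined" (U).
    """

    normal_max_kb: float = 5.5
    pathogenic_min_kb: float = 8.5

    def __post_init__(self) -> None:
        if not (0 < self.normal_max_kb <= self.pathogenic_min_kb):
            raise LocusConfigError(
                "require 0 < normal_max_kb <= pathogenic_min_kb, got "
                f"{self.normal_max_kb}, {self.pathogenic_min_kb}"
            )


@dataclass(frozen=True)
class LocusConfig:
    """A repeat locus: flanking anchor sequences, motifs and reference tract.

    Parameters
    ----------
    locus_id : str
        Identifier for the locus.
    left_flank, right_flank : str
        Unique anchor sequences immediately 5' and 3' of the repeat tract,
        in locus orientation. Each must be at least 100 bases long and must
        not contain two or more consecutive copies of any configured motif.
    motifs : tuple of str
        Repeat units in locus orientation, 5' to 3' order of the expected
        expansion structure. Every motif must be 5 bases.
    ref_assembly : str
        Assembly label for the reference coordinates.
    ref_start, ref_end : int
        1-based inclusive genomic coordinates of the reference repeat tract.
    thresholds : Thresholds
        Allele classification thresholds.
    """

    locus_id: str
    left_flank: str
    right_flank: str
    motifs: tuple[str, ...] = ("TTTTA", "TTTCA")
    ref_assembly: str = "GRCh37"
    ref_chrom: str = "chr5"
    ref_start: int = 10_356_460
    ref_end: int = 10_356_519
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self) -> None:
        object.__setattr__(self, "left_flank", self.left_flank.upper())
        object.__setattr__(self, "right_flank", self.right_flank.upper())
        object.__setattr__(self, "motifs", tuple(m.upper() for m in self.motifs))
        self._validate()

    def _validate(self) -> None:
        if self.ref_end < self.ref_start:
            raise LocusConfigError("ref_end must be >= ref_start")
        for m in self.motifs:
            if len(m) != 5:
                raise LocusConfigError(f"motif {m!r} is not 5 bases")
            if not set(m) <= VALID_BASES:
                raise LocusConfigError(f"motif {m!r} has non-ACGT characters")
        for name, flank in (("left_flank", self.left_flank), ("right_flank", self.right_flank)):
            if len(flank) < 100:
                raise LocusConfigError(f"{name} must be >= 100 bases, got {len(flank)}")
            if not set(flank) <= VALID_BASES:
                raise LocusConfigError(f"{name} has non-ACGT characters")
            for m in self.motifs:
                if m + m in flank:
                    raise LocusConfigError(
                        f"{name} contains a tandem run of motif {m}"
                    )

    @property
    def ref_tract_length(self) -> int:
        """Length in bases of the reference repeat tract (1-based inclusive)."""
        return self.ref_end - self.ref_start + 1

    def reference_tract(self) -> str:
        """Reference repeat tract built as a pure tandem of the first motif."""
        unit = self.motifs[0]
        n, rem = divmod(self.ref_tract_length, len(unit))
        return unit * n + unit[:rem]

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["motifs"] = list(self.motifs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LocusConfig":
        d = dict(d)
        thr = d.get("thresholds")
        if isinstance(thr, dict):
            d["thresholds"] = Thresholds(**thr)
        if "motifs" in d:
            d["motifs"] = tuple(d["motifs"])
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise LocusConfigError(f"unknown LocusConfig keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LocusConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


# Default anchors flanking the repeat tract. These are synthetic stand-ins
# with the properties anchoring relies on (unique, motif-free); real flank
# sequence can be supplied via a locus JSON.
DEFAULT_LEFT_FLANK = (
    "CGTACCGTCGTAGCCATGCTGCTTCATTGCAGGTTCTATTATCAGAGGAGCATCGACTGT"
    "CTGCAAAAGTATCCCTCACGGTAAGTACGGAGCGTCTAGCAGCAATTAGCGTCGGACGGG"
    "TTACACCACGAGATCGCCTGGGGCTCTGACAGTTAGCATAATTGCTAAGAATGACTTAGA"
    "CGCACCCCCTCACCAAGCTCAAATAGTCAAGAAGGCCTTCGACGTCTCCTCCTTTCGACG"
    "ACGGATCGGTGATGACAGTATAGACATCTTACTTGGCGTCCTGCTAAAATGTGGCGTCCT"
)
DEFAULT_RIGHT_FLANK = (
    "TTTCCTATTTAGCCTCTGTCTTACGTTTGACAATGACCCAGCCCTCGGCGGGTCGACTTG"
    "GTCCGGACGAATGAGCGTGCCTCTAACGTTCATACCAAATTAGCACTTAGTTCCTCACTT"
    "CACAATAGTTTGGCCCATTTAGCGTAGCGTTCACTGGCCCAGGCCGCCTAAGGGCCCTAA"
    "AGTGCATATGCGGTGCCGCTGTCGCATCCAGGCACGGCGGCTTGTTGCAAGCCCACTGTC"
    "AAATAAGTGGCGAGCACGTCGCCGTACAACCTTGGGTGCAGGCGTATATTTCCCTGCGAA"
)


def default_locus() -> LocusConfig:
    """Default pentanucleotide locus (intron-1 TTTTA/TTTCA site, GRCh37)."""
    return LocusConfig(
        locus_id="FAME3",
        left_flank=DEFAULT_LEFT_FLANK,
        right_flank=DEFAULT_RIGHT_FLANK,
    )
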