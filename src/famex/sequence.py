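"""Small sequence primitives shared across modules."""

from __future__ import annotations

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class AlphabetError(ValueError):
    """Raised on sequences with characters outside {A, C, G, T}."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def rotations(seq: str) -> list[str]:
    return [seq[i:] + seq[:i] for i in range(len(seq))]


def canonical_motif(motif: str) -> str:
    """Canonical form of a repeat unit.

    The lexicographically smallest string among all rotations of the motif
    and all rotations of its reverse complement (e.g. AAAAT for TTTTA and
    AAATG for TTTCA). Idempotent by construction.
    """
    motif = motif.upper()
    if not motif:
        raise AlphabetError("empty motif")
    if not set(motif) <= VALID_BASES:
        raise AlphabetError(f"motif {motif!r} has non-ACGT characters")
    return min(rotations(motif) + rotations(reverse_complement(motif)))
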