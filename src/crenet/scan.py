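"""Degenerate-pattern scanning of promoter sets.

PatMatch-style exact matching of IUPAC nucleotide patterns against
promoter sequences: every offset is tested, overlapping occurrences are
all reported, and an ``N`` in the *sequence* never matches any pattern
symbol (unknown bases cannot be claimed as motif instances).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping

__all__ = [
    "IUPAC_SETS",
    "MotifOccurrence",
    "IupacMatcher",
    "expand_iupac",
    "degeneracy",
    "expansion_words",
    "reverse_complement",
    "scan_promoters",
    "genes_with_motif",
]

#: Base sets denoted by each IUPAC nucleotide symbol.
IUPAC_SETS: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a sequence or IUPAC pattern."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_pattern(pattern: str) -> str:
    pattern = pattern.upper()
    if not pattern:
        raise ValueError("empty IUPAC pattern")
    bad = sorted(set(pattern) - set(IUPAC_SETS))
    if bad:
        raise ValueError(f"illegal IUPAC symbol(s) {bad!r} in pattern {pattern!r}")
    return pattern


def degeneracy(pattern: str) -> int:
    """Number of exact words the pattern expands to (product of symbol set sizes)."""
    pattern = _validate_pattern(pattern)
    n = 1
    for sym in pattern:
        n *= len(IUPAC_SETS[sym])
    return n


def expansion_words(pattern: str) -> list[str]:
    """All exact A/C/G/T words matching the pattern, lexicographic order."""
    pattern = _validate_pattern(pattern)
    return ["".join(w) for w in product(*(sorted(IUPAC_SETS[s]) for s in pattern))]


@dataclass(frozen=True)
class MotifOccurrence:
    """One exact match of a degenerate pattern inside a promoter.

    ``offset`` is 0-based on the forward promoter string regardless of
    strand; ``word`` is the matched promoter substring as written on the
    forward strand.
    """

    gene: str
    offset: int
    strand: str  # "+" or "-"
    word: str


class IupacMatcher:
    """Compiled membership predicate for one IUPAC pattern.

    Matching is implemented with a regex of per-position character
    classes inside a lookahead, so overlapping occurrences are found.
    Sequence ``N`` bases are absent from every class and therefore never
    match.
    """

    def __init__(self, pattern: str):
        self.pattern = _validate_pattern(pattern)
        self.width = len(self.pattern)
        self.degeneracy = degeneracy(self.pattern)
        body = "".join("[" + "".join(sorted(IUPAC_SETS[s])) + "]" for s in self.pattern)
        self._re = re.compile(r"(?=(" + body + r"))")

    def matches(self, word: str) -> bool:
        """Membership test: is ``word`` one of the pattern's expansions?"""
        if len(word) != self.width:
            return False
        return all(b in IUPAC_SETS[s] for b, s in zip(word.upper(), self.pattern))

    def finditer(self, seq: str) -> Iterable[tuple[int, str]]:
        """Yield (offset, matched word) for every occurrence, overlaps included."""
        for m in self._re.finditer(seq.upper()):
            yield m.start(), m.group(1)


def expand_iupac(pattern: str) -> IupacMatcher:
    """Compile an IUPAC pattern into a matcher (reports its degeneracy)."""
    return IupacMatcher(pattern)


def scan_promoters(
    promoters: Mapping[str, str],
    pattern: str | IupacMatcher,
    strands: str = "fwd",
) -> list[MotifOccurrence]:
    """Find all occurrences of ``pattern`` in every promoter.

    Parameters
    ----------
    promoters
        gene id -> uppercase promoter sequence (A/C/G/T/N).
    pattern
        IUPAC pattern string or a pre-compiled :class:`IupacMatcher`.
    strands
        ``"fwd"`` scans the given strand only (promoters are directional);
        ``"both"`` additionally scans the reverse complement, reporting
        forward-strand coordinates of the match.
    """
    if strands not in ("fwd", "both"):
        raise ValueError(f"strands must be 'fwd' or 'both', got {strands!r}")
    matcher = pattern if isinstance(pattern, IupacMatcher) else IupacMatcher(pattern)
    out: list[MotifOccurrence] = []
    rc_matcher = IupacMatcher(reverse_complement(matcher.pattern)) if strands == "both" else None
    for gene, seq in promoters.items():
        for off, word in matcher.finditer(seq):
            out.append(MotifOccurrence(gene, off, "+", word))
        if rc_matcher is not None:
            # a reverse-strand site is a forward match of the pattern's RC
            for off, word in rc_matcher.finditer(seq):
                out.append(MotifOccurrence(gene, off, "-", word))
    return out


def genes_with_motif(
    promoters: Mapping[str, str],
    pattern: str | IupacMatcher,
    strands: str = "fwd",
) -> set[str]:
    """Genes whose promoter carries >=1 occurrence (presence/absence semantics)."""
    return {occ.gene for occ in scan_promoters(promoters, pattern, strands)}
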