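"""The i-motif folding rule and the generalized tract/loop motif scanner.

The default rule is C5(N1-19C5)3: four tracts of five consecutive cytosines
separated by three loops of 1-19 arbitrary bases (loops may themselves
contain C, which can give rise to longer apparent tracts).  The same
machinery scans for the complementary G-run pattern on the minus strand.

Canonicalization choices
------------------------
* Hits on a strand are non-overlapping and found leftmost-first; scanning
  resumes after the end of each reported hit.
* Within a hit, each successive tract is placed at the earliest admissible
  position, i.e. the loop-length tuple is lexicographically minimal.
* The minus-strand search scans the reverse complement of the stored
  sequence with the same rule and mirrors coordinates back onto the forward
  axis, so plus/minus results are exact mirror images of each other.
* N never matches a tract base but is allowed inside loops.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .io import SequenceRecord

__all__ = [
    "MotifRule",
    "MotifHit",
    "TractLoopDecomposition",
    "revcomp",
    "find_hits",
    "scan_fasta",
    "decompose",
    "count_vs_loopmax",
    "expected_hits_iid",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_ORDER = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifRule:
    """Tract/loop folding-rule parameters.

    The defaults (C, 5, 4, 1, 19) encode the i-motif rule: four tracts of
    at least five cytosines with loops of one to nineteen bases.
    """

    base: str = "C"
    tract_len: int = 5
    n_tracts: int = 4
    loop_min: int = 1
    loop_max: int = 19

    def __post_init__(self) -> None:
        if self.base not in ("C", "G"):
            raise ValueError(f"rule base must be C or G, got {self.base!r}")
        if self.tract_len < 1:
            raise ValueError("tract_len must be >= 1")
        if self.n_tracts < 2:
            raise ValueError("n_tracts must be >= 2")
        if self.loop_min < 1:
            raise ValueError("loop_min must be >= 1")
        if self.loop_max < self.loop_min:
            raise ValueError("loop_max must be >= loop_min")

    @property
    def complement(self) -> "MotifRule":
        return replace(self, base="G" if self.base == "C" else "C")

    @property
    def min_span(self) -> int:
        return self.n_tracts * self.tract_len + (self.n_tracts - 1) * self.loop_min

    def pattern(self) -> re.Pattern[str]:
        """Compiled regex whose leftmost match has lexicographically minimal
        loops (lazy loop quantifiers)."""
        t, k = self.tract_len, self.n_tracts
        a, b = self.loop_min, self.loop_max
        return re.compile(
            f"{self.base}{{{t}}}(?:[ACGTN]{{{a},{b}}}?{self.base}{{{t}}}){{{k - 1}}}"
        )


@dataclass(frozen=True)
class MotifHit:
    """A located rule match with per-tract coordinates.

    Coordinates are on the forward axis of the source sequence.  For minus
    hits the i-motif-forming C-strand is the reverse complement of the
    stored slice; ``loop_lengths`` and ``matched_sequence`` follow the
    motif (C-rich) strand while ``tract_intervals`` are forward-axis
    ascending.
    """

    source_id: str
    start: int
    end: int
    strand: str
    tract_intervals: tuple[tuple[int, int], ...]
    loop_lengths: tuple[int, ...]
    matched_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"hit strand must be + or -, got {self.strand!r}")
        n = len(self.tract_intervals)
        if len(self.loop_lengths) != n - 1:
            raise ValueError("need exactly n_tracts - 1 loops")
        tract_total = sum(e - s for s, e in self.tract_intervals)
        if self.end - self.start != tract_total + sum(self.loop_lengths):
            raise ValueError("hit span inconsistent with tracts + loops")
        prev_end = self.start
        for s, e in self.tract_intervals:
            if s < prev_end or e <= s:
                raise ValueError("tract intervals must be ordered and disjoint")
            prev_end = e

    @property
    def total_loop_length(self) -> int:
        return sum(self.loop_lengths)


@dataclass(frozen=True)
class TractLoopDecomposition:
    """Tract/loop partition of a single oligonucleotide.

    ``fallback_used`` is True when the strict rule had no match and the
    tracts were instead taken as the n_tracts longest maximal base runs.
    """

    tract_intervals: tuple[tuple[int, int], ...]
    loop_lengths: tuple[int, ...]
    total_loop_length: int
    fallback_used: bool

    def __post_init__(self) -> None:
        if self.total_loop_length != sum(self.loop_lengths):
            raise ValueError("total_loop_length must equal sum(loop_lengths)")


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def _minimal_loops(s: str, start: int, rule: MotifRule) -> tuple[int, ...] | None:
    """Lexicographically smallest admissible loop tuple for a match anchored
    at ``start``, or None if no placement exists."""
    tract = rule.base * rule.tract_len
    if not s.startswith(tract, start):
        return None
    loops: list[int] = []

    def _extend(pos: int, tracts_done: int) -> bool:
        if tracts_done == rule.n_tracts:
            return True
        for loop in range(rule.loop_min, rule.loop_max + 1):
            nxt = pos + loop
            if nxt + rule.tract_len > len(s):
                break
            if s.startswith(tract, nxt):
                loops.append(loop)
                if _extend(nxt + rule.tract_len, tracts_done + 1):
                    return True
                loops.pop()
        return False

    if _extend(start + rule.tract_len, 1):
        return tuple(loops)
    return None


def _hit_from_loops(
    source_id: str, s: str, start: int, loops: tuple[int, ...], rule: MotifRule
) -> MotifHit:
    tracts = []
    pos = start
    for i in range(rule.n_tracts):
        tracts.append((pos, pos + rule.tract_len))
        pos += rule.tract_len
        if i < rule.n_tracts - 1:
            pos += loops[i]
    return MotifHit(
        source_id=source_id,
        start=start,
        end=pos,
        strand="+",
        tract_intervals=tuple(tracts),
        loop_lengths=loops,
        matched_sequence=s[start:pos],
    )


def find_hits(seq: SequenceRecord, rule: MotifRule | None = None) -> list[MotifHit]:
    """Non-overlapping, leftmost-first rule matches on the stored (+) strand.

    The regex engine locates each leftmost match span; the explicit
    backtracking placement then recovers the canonical (lexicographically
    minimal) loop decomposition within it.
    """
    rule = rule or MotifRule()
    s = seq.sequence
    hits: list[MotifHit] = []
    if rule.min_span > len(s):
        return hits
    for m in rule.pattern().finditer(s):
        loops = _minimal_loops(s, m.start(), rule)
        if loops is None:  # pragma: no cover - regex and placement agree
            raise AssertionError("regex match without admissible placement")
        hit = _hit_from_loops(seq.id, s, m.start(), loops, rule)
        if hit.end != m.end():  # pragma: no cover - both are lazy/minimal
            raise AssertionError("regex span disagrees with canonical placement")
        hits.append(hit)
    return hits


def _mirror_hit(hit: MotifHit, length: int) -> MotifHit:
    """Map a hit found on the reverse complement back to the forward axis."""
    tracts = tuple(
        sorted((length - e, length - s) for s, e in hit.tract_intervals)
    )
    return MotifHit(
        source_id=hit.source_id,
        start=length - hit.end,
        end=length - hit.start,
        strand="-",
        tract_intervals=tracts,
        loop_lengths=hit.loop_lengths,
        matched_sequence=hit.matched_sequence,
    )


def scan_fasta(
    records: Iterable[SequenceRecord],
    rule: MotifRule | None = None,
    strands: str = "both",
) -> list[MotifHit]:
    """Scan records on one or both strands.

    Minus-strand hits are found by scanning the reverse complement with the
    same rule and mirroring coordinates, so the reported start/end always
    refer to the stored forward axis while the matched sequence is the
    motif-forming strand.  Plus- and minus-strand hits are reported
    independently (no cross-strand merging).
    """
    rule = rule or MotifRule()
    if strands not in ("plus", "minus", "both"):
        raise ValueError(f"strands must be plus/minus/both, got {strands!r}")
    hits: list[MotifHit] = []
    for rec in records:
        per_record: list[MotifHit] = []
        if strands in ("plus", "both"):
            per_record.extend(find_hits(rec, rule))
        if strands in ("minus", "both"):
            rc = SequenceRecord(id=rec.id, sequence=revcomp(rec.sequence))
            length = len(rec.sequence)
            per_record.extend(_mirror_hit(h, length) for h in find_hits(rc, rule))
        per_record.sort(key=lambda h: (h.start, h.end, h.strand))
        hits.extend(per_record)
    return hits


# ---------------------------------------------------------------------------
# decomposition of single oligonucleotides
# ---------------------------------------------------------------------------


def decompose(seq: SequenceRecord, rule: MotifRule | None = None) -> TractLoopDecomposition:
    """Tract/loop decomposition of one oligonucleotide.

    If the strict rule matches anywhere, the leftmost canonical match is
    returned.  Otherwise the fallback takes the ``n_tracts`` longest maximal
    runs of the tract base (ties broken leftmost, runs shorter than two
    bases ineligible) in genomic order, with the inter-run gaps as loops.
    """
    rule = rule or MotifRule()
    s = seq.sequence
    for m in rule.pattern().finditer(s):
        loops = _minimal_loops(s, m.start(), rule)
        hit = _hit_from_loops(seq.id, s, m.start(), loops, rule)
        return TractLoopDecomposition(
            tract_intervals=hit.tract_intervals,
            loop_lengths=hit.loop_lengths,
            total_loop_length=sum(hit.loop_lengths),
            fallback_used=False,
        )

    runs = [
        (m.start(), m.end())
        for m in re.finditer(f"{rule.base}{{2,}}", s)
    ]
    if len(runs) < rule.n_tracts:
        raise ValueError(
            f"undecomposable: {seq.id!r} has only {len(runs)} runs of "
            f"{rule.base} with length >= 2 (need {rule.n_tracts})"
        )
    chosen = sorted(runs, key=lambda r: (-(r[1] - r[0]), r[0]))[: rule.n_tracts]
    chosen.sort()
    loop_lengths = tuple(
        chosen[i + 1][0] - chosen[i][1] for i in range(len(chosen) - 1)
    )
    return TractLoopDecomposition(
        tract_intervals=tuple(chosen),
        loop_lengths=loop_lengths,
        total_loop_length=sum(loop_lengths),
        fallback_used=True,
    )


# ---------------------------------------------------------------------------
# loop-length scaling
# ---------------------------------------------------------------------------


def count_vs_loopmax(
    records: Sequence[SequenceRecord],
    rule: MotifRule | None = None,
    loopmax_values: Sequence[int] = (7, 9, 11, 13, 15, 17, 19),
    strands: str = "both",
) -> dict[int, int]:
    """Total hit count as a function of the rule's maximum loop length."""
    rule = rule or MotifRule()
    for L in loopmax_values:
        if L < rule.loop_min:
            raise ValueError(
                f"loop_max {L} below loop_min {rule.loop_min}"
            )
    return {
        L: len(scan_fasta(records, replace(rule, loop_max=L), strands=strands))
        for L in loopmax_values
    }


def expected_hits_iid(
    rule: MotifRule,
    base_probs: Sequence[float],
    length: int,
) -> float:
    """Expected number of rule-match start positions in an i.i.d. sequence.

    Counts (start position, loop-length assignment) pairs: for every loop
    combination the probability that a match with exactly those loop lengths
    begins at a given position is p_base**(n_tracts * tract_len) (loop bases
    are unconstrained), so the expectation is that probability times the
    number of admissible (start, combination) pairs.  No first-occurrence or
    clump correction is applied.  For four tracts the number of loop
    combinations is (loop_max - loop_min + 1)**3 — the cubic law.
    """
    probs = np.asarray(base_probs, dtype=float)
    if probs.shape != (4,):
        raise ValueError("base_probs must be a length-4 vector (A, C, G, T)")
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("base probabilities must lie in [0, 1]")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("base probabilities must sum to 1 (within 1e-9)")
    p = float(probs[_BASE_ORDER.index(rule.base)])
    n_loops = rule.n_tracts - 1
    width = rule.loop_max - rule.loop_min + 1
    # distribution of the total loop length over all combinations
    counts = np.ones(width)
    for _ in range(n_loops - 1):
        counts = np.convolve(counts, np.ones(width))
    loop_sums = np.arange(n_loops * rule.loop_min, n_loops * rule.loop_max + 1)
    spans = rule.n_tracts * rule.tract_len + loop_sums
    positions = np.clip(length - spans + 1, 0, None)
    return float(p ** (rule.n_tracts * rule.tract_len) * np.dot(counts, positions))
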