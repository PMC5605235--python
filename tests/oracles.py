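"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: matches are found by
exhaustive enumeration of (start, loop-combination) placements, overlaps by
all-pairs checks, coverage by per-base counting.
"""

from __future__ import annotations

from itertools import product


def admissible_placements(s: str, rule) -> list[tuple[int, tuple[int, ...]]]:
    """Every (start, loops) pair matching the rule, by full enumeration."""
    t, k = rule.tract_len, rule.n_tracts
    a, b = rule.loop_min, rule.loop_max
    tract = rule.base * t
    out = []
    for start in range(len(s) - k * t - (k - 1) * a + 1):
        if s[start : start + t] != tract:
            continue
        for loops in product(range(a, b + 1), repeat=k - 1):
            pos = start + t
            ok = True
            for loop in loops:
                pos += loop
                if s[pos : pos + t] != tract:
                    ok = False
                    break
                pos += t
            if ok:
                out.append((start, loops))
    return out


def brute_find_hits(s: str, rule) -> list[tuple[int, int, tuple[int, ...]]]:
    """Non-overlapping leftmost-first matches with lexicographically minimal
    loops, selected from the full placement enumeration.

    Returns (start, end, loops) triples.
    """
    placements = sorted(admissible_placements(s, rule))
    hits = []
    cursor = 0
    for start, loops in placements:
        if start < cursor:
            continue
        end = start + rule.n_tracts * rule.tract_len + sum(loops)
        hits.append((start, end, loops))
        cursor = end
    return hits


def brute_overlap(hits, windows) -> tuple[int, dict[str, int]]:
    """All-pairs >=1 bp overlap count (hit-level and per-gene)."""
    per_gene: dict[str, int] = {}
    overlapping = 0
    for h in hits:
        touched = False
        for w in windows:
            if h.chrom == w.chrom and h.start < w.end and w.start < h.end:
                touched = True
                per_gene[w.name] = per_gene.get(w.name, 0) + 1
        if touched:
            overlapping += 1
    return overlapping, per_gene


def brute_coverage_fraction(windows, chrom_sizes) -> float:
    """Union coverage by marking every covered base."""
    covered = 0
    for chrom, size in chrom_sizes.items():
        marks = bytearray(size)
        for w in windows:
            if w.chrom == chrom:
                for i in range(w.start, min(w.end, size)):
                    marks[i] = 1
        covered += sum(marks)
    return covered / sum(chrom_sizes.values())


def bh_qvalues(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up by the textbook definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_top, idx in enumerate(reversed(order)):
        rank = m - rank_from_top
        running = min(running, p_values[idx] * m / rank)
        q[idx] = running
    return q
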