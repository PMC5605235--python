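"""Promoter-window construction and enrichment statistics.

Promoters are defined as the 1 kb region immediately upstream of a gene's
transcription start site (strand-aware).  Hit/promoter overlap is counted
with a >= 1 bp rule regardless of strand pairing, the chance expectation is
the union coverage fraction of the promoter windows, significance is a
1-df chi-squared goodness of fit over (overlapping, non-overlapping), and
GO-term over/under-representation uses two-sided Fisher's exact tests with
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FormatError, GenomicInterval

__all__ = [
    "TssRecord",
    "EnrichmentResult",
    "GoTermResult",
    "read_tss",
    "read_go_map",
    "promoter_windows",
    "overlap_hits",
    "genes_with_multiple_hits",
    "chance_expected_fraction",
    "chi_squared_enrichment",
    "bh_qvalues",
    "go_enrichment",
]


def bh_qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    Monotone in p-rank and bounded by 1; ties share one q-value.
    """
    _, q, _, _ = multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")
    return q


@dataclass(frozen=True)
class TssRecord:
    """A gene-level transcription start site (0-based position)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative TSS")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed/expected promoter-overlap counts with a chi-squared test."""

    observed: int
    total: int
    expected_fraction: float
    chi_squared: float
    p_value: float
    warnings: tuple[str, ...] = ()

    @property
    def observed_fraction(self) -> float:
        return self.observed / self.total


@dataclass(frozen=True)
class GoTermResult:
    """Fisher-test result for one GO term, with a BH-adjusted q-value."""

    go_id: str
    n_genes_with_term: int
    n_hit_genes_with_term: int
    p_value: float
    q_value: float
    direction: str


# ---------------------------------------------------------------------------
# annotation readers (TSV)
# ---------------------------------------------------------------------------


def read_tss(path: str | Path) -> list[TssRecord]:
    """Read a TSV with columns gene_id, chrom, tss_position_1based, strand.

    Positions are converted to the 0-based internal convention.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "chrom", "tss_position_1based", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            pos = int(row["tss_position_1based"])
        except ValueError as exc:
            raise FormatError(
                f"{path}: non-integer TSS at data row {int(i) + 1}"
            ) from exc
        records.append(
            TssRecord(
                gene_id=str(row["gene_id"]),
                chrom=str(row["chrom"]),
                tss=pos - 1,
                strand=str(row["strand"]),
            )
        )
    return records


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """Read a TSV with columns gene_id, go_id into a gene -> terms map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("gene_id", "go_id") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    go_map: dict[str, set[str]] = defaultdict(set)
    for gene, term in zip(df["gene_id"], df["go_id"]):
        go_map[str(gene)].add(str(term))
    return dict(go_map)


# ---------------------------------------------------------------------------
# promoter windows and overlap
# ---------------------------------------------------------------------------


def promoter_windows(
    tss_records: Iterable[TssRecord],
    upstream: int = 1000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """One promoter window per gene: the ``upstream`` bases 5' of the TSS.

    Plus-strand genes get [tss - upstream, tss); minus-strand genes get
    [tss + 1, tss + 1 + upstream).  Windows are clipped to chromosome
    bounds; windows emptied by clipping are dropped.
    """
    if upstream < 1:
        raise ValueError("upstream must be >= 1")
    chrom_sizes = dict(chrom_sizes or {})
    windows: list[GenomicInterval] = []
    for rec in tss_records:
        if rec.chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {rec.chrom!r} for gene {rec.gene_id!r}")
        size = chrom_sizes[rec.chrom]
        if rec.strand == "+":
            start, end = rec.tss - upstream, rec.tss
        else:
            start, end = rec.tss + 1, rec.tss + 1 + upstream
        start, end = max(0, start), min(size, end)
        if end <= start:
            continue
        windows.append(
            GenomicInterval(
                chrom=rec.chrom, start=start, end=end,
                strand=rec.strand, name=rec.gene_id,
            )
        )
    return windows


def overlap_hits(
    hits: Sequence[GenomicInterval],
    windows: Sequence[GenomicInterval],
) -> tuple[int, dict[str, int]]:
    """Count hits overlapping any promoter window (>= 1 bp, strand-blind).

    Each hit contributes at most 1 to the overlapping-hit count but
    increments the per-gene count of every window it touches.  Implemented
    with a per-chromosome binary search over window starts (the brute-force
    pairwise check is kept in the test suite as the oracle).
    """
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for w in windows:
        by_chrom[w.chrom].append(w)
    index: dict[str, tuple[list[int], list[GenomicInterval], int]] = {}
    for chrom, ws in by_chrom.items():
        ws.sort(key=lambda w: (w.start, w.end))
        starts = [w.start for w in ws]
        max_len = max(len(w) for w in ws)
        index[chrom] = (starts, ws, max_len)

    per_gene: dict[str, int] = defaultdict(int)
    overlapping = 0
    for hit in hits:
        if hit.chrom not in index:
            continue
        starts, ws, max_len = index[hit.chrom]
        hi = bisect_left(starts, hit.end)  # windows starting before hit.end
        lo = bisect_right(starts, hit.start - max_len)
        touched = False
        for w in ws[lo:hi]:
            if w.end > hit.start:  # start < hit.end is given by the slice
                touched = True
                per_gene[w.name] += 1
        if touched:
            overlapping += 1
    return overlapping, dict(per_gene)


def genes_with_multiple_hits(per_gene_counts: Mapping[str, int]) -> int:
    """Number of genes whose promoter contains two or more hits."""
    return sum(1 for count in per_gene_counts.values() if count >= 2)


def chance_expected_fraction(
    windows: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
) -> float:
    """Fraction of the genome covered by the union of promoter windows."""
    genome_length = sum(chrom_sizes.values())
    if genome_length <= 0:
        raise ValueError("total genome length must be positive")
    covered = 0
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for w in windows:
        by_chrom[w.chrom].append(w)
    for chrom, ws in by_chrom.items():
        ws.sort(key=lambda w: w.start)
        cur_start, cur_end = ws[0].start, ws[0].end
        for w in ws[1:]:
            if w.start <= cur_end:
                cur_end = max(cur_end, w.end)
            else:
                covered += cur_end - cur_start
                cur_start, cur_end = w.start, w.end
        covered += cur_end - cur_start
    return covered / genome_length


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def chi_squared_enrichment(
    observed: int,
    total: int,
    expected_fraction: float,
) -> EnrichmentResult:
    """1-df goodness-of-fit over the (overlapping, non-overlapping) cells.

    No continuity correction is applied.  If an expected cell is below 1 a
    warning is attached to the result rather than raising.
    """
    if not 0 < expected_fraction < 1:
        raise ValueError("expected_fraction must lie strictly between 0 and 1")
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= observed <= total:
        raise ValueError("observed must lie in [0, total]")
    expected = np.array(
        [expected_fraction * total, (1.0 - expected_fraction) * total]
    )
    obs = np.array([observed, total - observed], dtype=float)
    chi2 = float(np.sum((obs - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    warnings: tuple[str, ...] = ()
    if expected.min() < 1:
        warnings = (
            f"expected cell count {expected.min():.3g} < 1; "
            "chi-squared approximation unreliable",
        )
    return EnrichmentResult(
        observed=observed,
        total=total,
        expected_fraction=expected_fraction,
        chi_squared=chi2,
        p_value=p,
        warnings=warnings,
    )


def go_enrichment(
    hit_genes: set[str],
    universe_genes: set[str],
    go_map: Mapping[str, set[str]],
    min_genes: int = 100,
) -> list[GoTermResult]:
    """Per-term 2x2 Fisher's exact tests with BH step-up q-values.

    Terms applicable to fewer than ``min_genes`` universe genes are excluded
    before testing; q-values are adjusted over the tested terms only.
    Direction is 'enriched' when the observed hit-gene count exceeds the
    expectation len(hit)*len(term)/len(universe), 'depleted' otherwise.
    """
    if not universe_genes:
        raise ValueError("empty gene universe")
    if not hit_genes <= universe_genes:
        raise ValueError("hit_genes must be a subset of universe_genes")

    term_genes: dict[str, set[str]] = defaultdict(set)
    for gene in universe_genes:
        for term in go_map.get(gene, ()):
            term_genes[term].add(gene)
    tested = {
        term: genes
        for term, genes in term_genes.items()
        if len(genes) >= min_genes
    }
    if not tested:
        return []

    n_universe = len(universe_genes)
    n_hit = len(hit_genes)
    terms = sorted(tested)
    p_values = []
    counts = []
    for term in terms:
        genes = tested[term]
        a = len(hit_genes & genes)
        b = n_hit - a
        c = len(genes) - a
        d = n_universe - n_hit - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        p_values.append(float(p))
        counts.append((len(genes), a))
    q_values = bh_qvalues(p_values)

    results = []
    for term, p, q, (n_term, n_hit_term) in zip(terms, p_values, q_values, counts):
        expected = n_hit * n_term / n_universe
        results.append(
            GoTermResult(
                go_id=term,
                n_genes_with_term=n_term,
                n_hit_genes_with_term=n_hit_term,
                p_value=p,
                q_value=float(q),
                direction="enriched" if n_hit_term > expected else "depleted",
            )
        )
    results.sort(key=lambda r: (r.p_value, r.go_id))
    return results
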