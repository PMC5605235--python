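"""Per-sequence structural features and their correlation with stability.

The feature of interest is the total loop length — the sum of all loop
bases of a candidate sequence — which is compared against measured
transitional pH and melting temperature across a panel of
oligonucleotides.  Both quantities fall with increasing loop length in
genomic i-motif candidates.

Two operationalizations of "loop bases" are supported:

* ``loop_basis="non_tract_bases"`` (default) counts every base that is not
  the tract base: in a cytosine-rich candidate each cytosine can in
  principle join the intercalated C:C+ core, so the loop bases are exactly
  the non-cytosine bases.  This parameter-free convention reproduces the
  published loop-length correlations of the genomic candidate panel.
* ``loop_basis="decomposition"`` sums the three loop lengths of the
  canonical tract/loop decomposition (leftmost-greedy rule match, with the
  longest-runs fallback where the strict rule fails).  Loops placed under
  the rule may themselves contain cytosine, so this count is smaller for
  sequences with extended C runs; it yields the same correlation signs
  with more modest magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SequenceRecord
from .scan import MotifRule, decompose

__all__ = [
    "CorrelationResult",
    "total_loop_length",
    "build_feature_table",
    "pearson",
]

LOOP_BASES_CONVENTIONS = ("non_tract_bases", "decomposition")


@dataclass(frozen=True)
class CorrelationResult:
    """A Pearson product-moment coefficient with its sample size."""

    r: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("r must lie in [-1, 1]")
        if self.n < 3:
            raise ValueError("need n >= 3")


def total_loop_length(
    record: SequenceRecord,
    rule: MotifRule | None = None,
    loop_basis: str = "non_tract_bases",
) -> tuple[int, bool]:
    """Total loop length of one candidate, with a fallback flag.

    Returns (loop_bases, fallback_used); the flag is only meaningful for
    the decomposition basis (True when the strict rule had no match).
    """
    rule = rule or MotifRule()
    if loop_basis == "non_tract_bases":
        return sum(ch != rule.base for ch in record.sequence), False
    if loop_basis == "decomposition":
        dec = decompose(record, rule)
        return dec.total_loop_length, dec.fallback_used
    raise ValueError(
        f"loop_basis must be one of {LOOP_BASES_CONVENTIONS}, got {loop_basis!r}"
    )


def build_feature_table(
    records: Sequence[SequenceRecord],
    rule: MotifRule | None = None,
    measurements: pd.DataFrame | None = None,
    loop_basis: str = "non_tract_bases",
) -> pd.DataFrame:
    """Join per-sequence loop lengths with measured stabilities.

    ``measurements`` needs columns (id, ph_t, tm); where a sequence showed
    two melting transitions the caller supplies the larger (final
    unfolding) Tm.  Output columns: sequence_id, total_loop_length,
    ph_t, tm, fallback_used.
    """
    rule = rule or MotifRule()
    by_id = {rec.id: rec for rec in records}
    if measurements is None:
        measurements = pd.DataFrame(
            {"id": list(by_id), "ph_t": np.nan, "tm": np.nan}
        )
    missing = [i for i in measurements["id"] if i not in by_id]
    if missing:
        raise ValueError(f"no sequence for measurement id(s): {', '.join(missing)}")
    rows = []
    for _, m in measurements.iterrows():
        loops, fallback = total_loop_length(by_id[m["id"]], rule, loop_basis)
        rows.append(
            {
                "sequence_id": m["id"],
                "total_loop_length": loops,
                "ph_t": float(m["ph_t"]),
                "tm": float(m["tm"]),
                "fallback_used": fallback,
            }
        )
    return pd.DataFrame(rows)


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with pairwise deletion of missing values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    r, _ = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=len(x))
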