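"""CD pH-titration fitting and CD spectrum classification.

The transitional pH (pH_T) — the pH at which a cytosine-rich sequence is
50% folded — is the inflection point of the ellipticity-at-288-nm vs pH
curve.  The fitted model is a symmetric four-parameter logistic with a
base-10 kernel (Henderson-Hasselbalch-like):

    E(pH) = e_unfolded + (e_folded - e_unfolded) / (1 + 10**(slope*(pH - pH_T)))

whose inflection is pH_T analytically, so the reported quantity is
invariant under affine transforms of the ellipticity scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .io import CurveTable, Spectrum

__all__ = [
    "TitrationSeries",
    "TitrationFit",
    "titration_model",
    "series_from_table",
    "fit_titration",
    "folded_fraction",
    "classify_cd_spectrum",
]

# classification windows: folded +288/-260 nm, unfolded +273/-250 nm;
# +/- 6 nm keeps the two positive windows disjoint
FOLDED_POS_NM = 288.0
FOLDED_NEG_NM = 260.0
UNFOLDED_POS_NM = 273.0
UNFOLDED_NEG_NM = 250.0
CD_WINDOW_NM = 6.0

_SLOPE_STARTS = (1.0, 2.0, 4.0)


@dataclass(frozen=True)
class TitrationSeries:
    """Ellipticity at 288 nm versus pH for one sequence."""

    series_id: str
    ph: np.ndarray
    ellipticity_288: np.ndarray

    def __post_init__(self) -> None:
        ph = np.asarray(self.ph, dtype=float)
        e = np.asarray(self.ellipticity_288, dtype=float)
        if ph.shape != e.shape or ph.ndim != 1:
            raise ValueError(f"series {self.series_id!r}: shape mismatch")
        order = np.argsort(ph)
        ph, e = ph[order], e[order]
        if len(np.unique(ph)) < 4:
            raise ValueError(
                f"series {self.series_id!r}: need >= 4 distinct pH points"
            )
        if ph.min() < 0 or ph.max() > 14:
            raise ValueError(f"series {self.series_id!r}: pH outside [0, 14]")
        object.__setattr__(self, "ph", ph)
        object.__setattr__(self, "ellipticity_288", e)


@dataclass(frozen=True)
class TitrationFit:
    """Fitted sigmoid parameters; ``ph_t`` is the inflection point."""

    series_id: str
    ph_t: float
    slope: float
    e_folded: float
    e_unfolded: float
    rmse: float


def titration_model(
    ph: np.ndarray | float,
    ph_t: float,
    slope: float,
    e_folded: float,
    e_unfolded: float,
) -> np.ndarray | float:
    """Four-parameter logistic in pH (base-10 kernel)."""
    return e_unfolded + (e_folded - e_unfolded) / (
        1.0 + 10.0 ** (slope * (np.asarray(ph, dtype=float) - ph_t))
    )


def series_from_table(table: CurveTable) -> list[TitrationSeries]:
    """Split a cd_titration CurveTable into per-sequence series."""
    if table.kind != "cd_titration":
        raise ValueError(f"not a cd_titration table (kind={table.kind!r})")
    out = []
    for sid, grp in table.data.groupby("series_id", sort=True):
        out.append(
            TitrationSeries(
                series_id=str(sid),
                ph=grp["x"].to_numpy(),
                ellipticity_288=grp["y"].to_numpy(),
            )
        )
    return out


def fit_titration(series: TitrationSeries) -> TitrationFit:
    """Least-squares sigmoid fit of a pH titration.

    Initialization: the plateaus from the means of the two most acidic /
    most basic points, pH_T from the pH whose ellipticity is nearest the
    midpoint, and a small multistart over steepness (1, 2, 4); the start
    with the best RMSE wins, ties going to the smallest slope.  pH_T is
    constrained to the data range extended by one unit.

    Raises ValueError("no transition") for flat series.
    """
    ph, e = series.ph, series.ellipticity_288
    span = float(np.ptp(e))
    if span < 1e-12:
        raise ValueError(f"series {series.series_id!r}: no transition (flat)")

    e_f0 = float(np.mean(e[:2]))
    e_u0 = float(np.mean(e[-2:]))
    mid = 0.5 * (e_f0 + e_u0)
    ph_t0 = float(ph[int(np.argmin(np.abs(e - mid)))])
    lo = np.array([ph.min() - 1.0, -50.0, -np.inf, -np.inf])
    hi = np.array([ph.max() + 1.0, 50.0, np.inf, np.inf])

    def residuals(theta: np.ndarray) -> np.ndarray:
        return titration_model(ph, *theta) - e

    best: tuple[float, float, np.ndarray] | None = None
    for s0 in _SLOPE_STARTS:
        x0 = np.clip(np.array([ph_t0, s0, e_f0, e_u0]), lo, hi)
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi))
        except Exception:
            continue
        rmse = float(np.sqrt(np.mean(sol.fun**2)))
        key = (round(rmse, 12), abs(float(sol.x[1])))
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], sol.x)
    if best is None:
        raise ValueError(f"series {series.series_id!r}: fit failed")
    ph_t, slope, e_folded, e_unfolded = (float(v) for v in best[2])
    rmse = float(np.sqrt(np.mean(residuals(best[2]) ** 2)))
    if abs(e_folded - e_unfolded) < max(1e-9, 3.0 * rmse):
        raise ValueError(f"series {series.series_id!r}: no transition")
    return TitrationFit(
        series_id=series.series_id,
        ph_t=ph_t,
        slope=slope,
        e_folded=e_folded,
        e_unfolded=e_unfolded,
        rmse=rmse,
    )


def folded_fraction(fit: TitrationFit, ph: np.ndarray | float) -> np.ndarray | float:
    """Fraction folded at a given pH; exactly 0.5 at pH_T."""
    return 1.0 / (1.0 + 10.0 ** (fit.slope * (np.asarray(ph, dtype=float) - fit.ph_t)))


def classify_cd_spectrum(spectrum: Spectrum) -> str:
    """Classify a CD scan as folded_i_motif, unfolded or other.

    Folded i-motif: positive global maximum within 288 +/- 6 nm and a
    negative minimum within 260 +/- 6 nm.  Unfolded: positive maximum
    within 273 +/- 6 nm and negative minimum within 250 +/- 6 nm.
    """
    wl, v = spectrum.wavelength, spectrum.values
    if wl.min() > 240 or wl.max() < 320:
        raise ValueError("spectrum must cover the 240-320 nm band")
    peak_idx = int(np.argmax(v))
    peak_nm, peak_val = float(wl[peak_idx]), float(v[peak_idx])
    if peak_val <= 0:
        return "other"

    def window_min(center: float) -> float:
        mask = (wl >= center - CD_WINDOW_NM) & (wl <= center + CD_WINDOW_NM)
        return float(v[mask].min()) if mask.any() else np.inf

    if abs(peak_nm - FOLDED_POS_NM) <= CD_WINDOW_NM and window_min(FOLDED_NEG_NM) < 0:
        return "folded_i_motif"
    if abs(peak_nm - UNFOLDED_POS_NM) <= CD_WINDOW_NM and window_min(UNFOLDED_NEG_NM) < 0:
        return "unfolded"
    return "other"
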