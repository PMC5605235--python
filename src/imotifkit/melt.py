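"""UV melting-curve analysis and thermal difference spectra.

Melting/annealing temperatures are extracted by the first-derivative
method: the absorbance-vs-temperature curve (295 nm for i-motif work) is
mildly smoothed, differentiated on its temperature grid, and up to two
derivative extrema are reported as transitions.  Thermal difference
spectra (TDS) are the unfolded-minus-folded absorbance difference
(95 degC - 4 degC) over 220-320 nm, normalized so the maximum change is
+1; the i-motif signature is a positive peak at 240 nm with a negative
peak at 295 nm.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .io import CurveTable, Spectrum

__all__ = [
    "AnalysisWarning",
    "MeltCurve",
    "MeltResult",
    "Tds",
    "curves_from_table",
    "average_replicates",
    "detect_transitions",
    "analyze_melt",
    "hysteresis",
    "compute_tds",
    "classify_tds",
]

# smoothing window/order, peak prominence fraction, classification
# windows and depth
SMOOTH_WINDOW = 7
SMOOTH_ORDER = 2
PROMINENCE_FRACTION = 0.25
TDS_POSITIVE_NM = 240.0
TDS_NEGATIVE_NM = 295.0
TDS_WINDOW_NM = 10.0
TDS_NEGATIVE_DEPTH = -0.2


class AnalysisWarning(UserWarning):
    """Non-fatal analysis condition (flat curve, missing transition...)."""


@dataclass(frozen=True)
class MeltCurve:
    """A temperature-absorbance series for one direction and replicate."""

    series_id: str
    direction: str
    temperature: np.ndarray
    absorbance: np.ndarray
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.direction not in ("melt", "anneal"):
            raise ValueError("direction must be 'melt' or 'anneal'")
        t = np.asarray(self.temperature, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError(f"curve {self.series_id!r}: shape mismatch")
        order = np.argsort(t)
        t, a = t[order], a[order]
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"curve {self.series_id!r}: duplicated temperature points"
            )
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "absorbance", a)

    def __len__(self) -> int:
        return len(self.temperature)


@dataclass(frozen=True)
class MeltResult:
    """Extracted transition temperatures for one series.

    ``tm_values``/``ta_values`` are ascending; the ``*_primary`` fields hold
    the largest-amplitude transition of each direction, which anchors the
    hysteresis (a single annealing temperature is conventionally reported
    even for two-step melts).
    """

    series_id: str
    tm_values: tuple[float, ...] = ()
    ta_values: tuple[float, ...] = ()
    tm_primary: float | None = None
    ta_primary: float | None = None
    hysteresis: float = float("nan")
    n_transitions: int = 0
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class Tds:
    """A normalized thermal difference spectrum with its classification."""

    series_id: str
    wavelength: np.ndarray
    delta_abs: np.ndarray
    label: str = "other"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        d = np.asarray(self.delta_abs, dtype=float)
        if wl.shape != d.shape:
            raise ValueError("wavelength/delta shape mismatch")
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "delta_abs", d)


# ---------------------------------------------------------------------------
# curve plumbing
# ---------------------------------------------------------------------------


def curves_from_table(table: CurveTable) -> list[MeltCurve]:
    """Split a melt CurveTable into one MeltCurve per (series, direction,
    replicate)."""
    if table.kind != "melt":
        raise ValueError(f"not a melt table (kind={table.kind!r})")
    curves = []
    for (sid, direction, replicate), grp in table.iter_series():
        if direction == "none":
            direction = "melt"
        curves.append(
            MeltCurve(
                series_id=str(sid),
                direction=str(direction),
                temperature=grp["x"].to_numpy(),
                absorbance=grp["y"].to_numpy(),
                replicate=int(replicate),
            )
        )
    return curves


def average_replicates(curves: Sequence[MeltCurve]) -> MeltCurve:
    """Average replicate curves (same series/direction) on a shared grid."""
    if not curves:
        raise ValueError("no curves to average")
    first = curves[0]
    for c in curves[1:]:
        if c.series_id != first.series_id or c.direction != first.direction:
            raise ValueError("can only average replicates of one series/direction")
        if c.temperature.shape != first.temperature.shape or not np.allclose(
            c.temperature, first.temperature
        ):
            raise ValueError("replicates must share a temperature grid")
    mean_abs = np.mean([c.absorbance for c in curves], axis=0)
    return replace(first, absorbance=mean_abs, replicate=1)


# ---------------------------------------------------------------------------
# first-derivative transition detection
# ---------------------------------------------------------------------------


def _refine_peak(t: np.ndarray, s: np.ndarray, idx: int) -> float:
    """Sub-grid peak position by a quadratic fit through three points."""
    if idx == 0 or idx == len(t) - 1:
        return float(t[idx])
    y0, y1, y2 = s[idx - 1], s[idx], s[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(t[idx])
    offset = 0.5 * (y0 - y2) / denom
    offset = float(np.clip(offset, -0.5, 0.5))
    step = 0.5 * (t[idx + 1] - t[idx - 1])
    return float(t[idx] + offset * step)


def detect_transitions(curve: MeltCurve, max_transitions: int = 2) -> MeltResult:
    """Transition temperatures of one curve by the first-derivative method.

    The curve is smoothed with a 7-point, order-2 polynomial filter, dA/dT
    is taken on the temperature grid and peaks of \\|dA/dT\\| with prominence
    of at least 25% of the largest extremum are kept (largest first, at
    most ``max_transitions``), reported ascending by temperature.  At
    295 nm the i-motif transition is a hypochromic drop, hence the absolute
    value.  A flat curve yields no transitions plus a warning.
    """
    if max_transitions < 1:
        raise ValueError("max_transitions must be >= 1")
    t, a = curve.temperature, curve.absorbance
    if len(t) < 10:
        raise ValueError(f"curve {curve.series_id!r}: need >= 10 points")
    if t[-1] - t[0] < 20:
        raise ValueError(
            f"curve {curve.series_id!r}: temperature span must be >= 20 degC"
        )
    window = min(SMOOTH_WINDOW, len(a) if len(a) % 2 else len(a) - 1)
    smooth = savgol_filter(a, window_length=window, polyorder=SMOOTH_ORDER)
    deriv = np.gradient(smooth, t)
    s = np.abs(deriv)

    warn_messages: list[str] = []
    mad = float(np.median(np.abs(s - np.median(s))))
    flat_floor = float(np.median(s)) + max(5 * 1.4826 * mad, 1e-9)
    if s.max() <= flat_floor:
        msg = f"curve {curve.series_id!r}: no transition above noise floor"
        _warnings.warn(msg, AnalysisWarning, stacklevel=2)
        return MeltResult(series_id=curve.series_id, warnings=(msg,))

    peaks, props = find_peaks(s, prominence=PROMINENCE_FRACTION * s.max())
    if len(peaks) == 0:
        # a transition at the very edge of the grid has no interior peak
        msg = f"curve {curve.series_id!r}: no interior derivative extremum"
        _warnings.warn(msg, AnalysisWarning, stacklevel=2)
        return MeltResult(series_id=curve.series_id, warnings=(msg,))
    order = np.argsort(s[peaks])[::-1][:max_transitions]
    kept = peaks[order]
    temps = [_refine_peak(t, s, i) for i in kept]
    primary = temps[0]
    temps_sorted = tuple(sorted(temps))
    result = MeltResult(
        series_id=curve.series_id,
        n_transitions=len(temps_sorted),
        warnings=tuple(warn_messages),
    )
    if curve.direction == "anneal":
        return replace(result, ta_values=temps_sorted, ta_primary=primary)
    return replace(result, tm_values=temps_sorted, tm_primary=primary)


def hysteresis(tm: float, ta: float) -> float:
    """Melting minus annealing temperature."""
    if not (np.isfinite(tm) and np.isfinite(ta)):
        raise ValueError("tm and ta must be finite")
    return tm - ta


def analyze_melt(
    melt_curve: MeltCurve,
    anneal_curve: MeltCurve | None = None,
    max_transitions: int = 2,
) -> MeltResult:
    """Full melt/anneal analysis of one series.

    Hysteresis pairs the largest-amplitude melt transition with the
    largest-amplitude anneal transition.
    """
    melt_res = detect_transitions(melt_curve, max_transitions)
    if anneal_curve is None:
        return melt_res
    anneal_res = detect_transitions(anneal_curve, max_transitions)
    hyst = float("nan")
    if melt_res.tm_primary is not None and anneal_res.ta_primary is not None:
        hyst = hysteresis(melt_res.tm_primary, anneal_res.ta_primary)
    return MeltResult(
        series_id=melt_curve.series_id,
        tm_values=melt_res.tm_values,
        ta_values=anneal_res.ta_values,
        tm_primary=melt_res.tm_primary,
        ta_primary=anneal_res.ta_primary,
        hysteresis=hyst,
        n_transitions=melt_res.n_transitions,
        warnings=melt_res.warnings + anneal_res.warnings,
    )


# ---------------------------------------------------------------------------
# thermal difference spectra
# ---------------------------------------------------------------------------


def compute_tds(spectrum_hot: Spectrum, spectrum_cold: Spectrum) -> Tds:
    """Unfolded-minus-folded difference spectrum, normalized to max +1.

    Both spectra must share a wavelength grid covering 220-320 nm; the
    difference is restricted to that band before normalization.  Adding a
    constant offset to both spectra leaves the result unchanged.
    """
    wl_h, wl_c = spectrum_hot.wavelength, spectrum_cold.wavelength
    if wl_h.shape != wl_c.shape or not np.allclose(wl_h, wl_c):
        raise ValueError("hot and cold spectra must share a wavelength grid")
    if wl_h.min() > 220 or wl_h.max() < 320:
        raise ValueError("spectra must cover the 220-320 nm band")
    band = (wl_h >= 220) & (wl_h <= 320)
    wl = wl_h[band]
    delta = spectrum_hot.values[band] - spectrum_cold.values[band]
    peak = float(delta.max())
    if peak <= 0 or peak < 1e-12:
        raise ValueError("no positive difference to normalize")
    delta = delta / peak
    tds = Tds(series_id=spectrum_hot.series_id, wavelength=wl, delta_abs=delta)
    return replace(tds, label=classify_tds(tds))


def classify_tds(tds: Tds) -> str:
    """Classify a normalized TDS as i_motif, random_coil or other.

    i_motif: the global positive extremum lies within 240 +/- 10 nm AND the
    minimum within 295 +/- 10 nm is at most -0.2.  random_coil: no value
    at or below -0.2 anywhere in 280-320 nm.  Everything else: other.
    """
    wl, d = tds.wavelength, tds.delta_abs
    pos_nm = float(wl[int(np.argmax(d))])
    neg_window = (wl >= TDS_NEGATIVE_NM - TDS_WINDOW_NM) & (
        wl <= TDS_NEGATIVE_NM + TDS_WINDOW_NM
    )
    red_band = (wl >= 280) & (wl <= 320)
    neg_min = float(d[neg_window].min()) if neg_window.any() else np.inf
    red_min = float(d[red_band].min()) if red_band.any() else np.inf
    if abs(pos_nm - TDS_POSITIVE_NM) <= TDS_WINDOW_NM and neg_min <= TDS_NEGATIVE_DEPTH:
        return "i_motif"
    if red_min > TDS_NEGATIVE_DEPTH:
        return "random_coil"
    return "other"
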