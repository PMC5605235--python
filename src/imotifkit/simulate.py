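"""Seeded generators with known ground truth for every pipeline stage.

Each generator is a pure function of its arguments including the seed:
i.i.d. background genomes with planted tract/loop motifs, random TSS/GO
annotations, two-state van't Hoff melting curves with sloping baselines
(annealing hysteresis modelled as a phenomenological downshift of the
apparent midpoint), folded/unfolded absorbance spectrum pairs carrying the
i-motif TDS signature (+240 nm / -295 nm), CD scans of the folded
(+288/-260 nm) and unfolded (+273/-250 nm) states, and sigmoidal
ellipticity-vs-pH titrations with a known transitional pH.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .enrichment import TssRecord
from .io import GenomicInterval, SequenceRecord, Spectrum
from .melt import MeltCurve
from .scan import MotifRule, revcomp, scan_fasta
from .titration import TitrationSeries, titration_model

__all__ = [
    "R_GAS",
    "PlantSpec",
    "PlantedTruth",
    "TwoStateParams",
    "simulate_genome",
    "simulate_annotation",
    "simulate_melt_curve",
    "simulate_spectra",
    "simulate_cd_spectrum",
    "simulate_titration",
]

R_GAS = 8.314  # J/(mol*K)
_BASES = np.array(list("ACGT"))
_LOOP_BASES = ("A", "T")  # loop alphabet that cannot extend C or G tracts


@dataclass(frozen=True)
class PlantSpec:
    """Blueprint for one planted tract/loop motif (given on the C-strand)."""

    tract_len: int = 5
    n_tracts: int = 4
    loop_lengths: tuple[int, ...] = (3, 3, 3)
    base: str = "C"

    def __post_init__(self) -> None:
        if len(self.loop_lengths) != self.n_tracts - 1:
            raise ValueError("need n_tracts - 1 loop lengths")

    @property
    def span(self) -> int:
        return self.n_tracts * self.tract_len + sum(self.loop_lengths)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth coordinates and sequences of the planted motifs."""

    intervals: tuple[GenomicInterval, ...]
    sequences: tuple[str, ...]


@dataclass(frozen=True)
class TwoStateParams:
    """Two-state van't Hoff component of a melting curve.

    ``dH`` is the apparent folding enthalpy (negative: folding is
    exothermic).  Baselines are (intercept AU, slope AU/degC) for the
    folded and unfolded states at the monitoring wavelength.
    """

    tm: float
    dH: float = -700e3
    baseline_folded: tuple[float, float] = (0.52, 1e-4)
    baseline_unfolded: tuple[float, float] = (0.44, 3e-4)
    noise_sd: float = 0.002
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dH >= 0:
            raise ValueError("dH must be negative (folding exothermic)")

    def theta(self, t_celsius: np.ndarray, tm_eff: float | None = None) -> np.ndarray:
        """Folded fraction; exactly 0.5 at the (effective) midpoint."""
        tm_k = (self.tm if tm_eff is None else tm_eff) + 273.15
        t_k = np.asarray(t_celsius, dtype=float) + 273.15
        return 1.0 / (1.0 + np.exp((self.dH / R_GAS) * (1.0 / t_k - 1.0 / tm_k)))


# ---------------------------------------------------------------------------
# genomes and annotations
# ---------------------------------------------------------------------------


def _build_motif(spec: PlantSpec, rng: np.random.Generator) -> str:
    tract = spec.base * spec.tract_len
    parts = [tract]
    for loop_len in spec.loop_lengths:
        parts.append("".join(rng.choice(_LOOP_BASES, size=loop_len)))
        parts.append(tract)
    return "".join(parts)


def simulate_genome(
    length: int,
    base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    planted: Sequence[tuple[PlantSpec, str]] = (),
    min_gap: int = 50,
    seed: int = 0,
    rule: MotifRule | None = None,
    record_id: str = "synthetic_genome",
) -> tuple[SequenceRecord, PlantedTruth]:
    """An i.i.d. background genome with planted motifs at known positions.

    Plants are placed in order with random gaps of at least ``min_gap``
    (>= 1); loop bases are drawn from {A, T} so loops cannot extend tracts,
    and each plant is flanked by one non-tract base.  After assembly the
    genome is scanned with ``rule`` and the background is re-drawn (plants
    kept) until the scan recovers exactly the planted truth, so the truth
    table stays exact for scanner tests.
    """
    rng = np.random.default_rng(seed)
    probs = np.asarray(base_probs, dtype=float)
    if probs.shape != (4,) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("base_probs must be 4 probabilities summing to 1")
    min_gap = max(1, int(min_gap))
    rule = rule or MotifRule()

    motifs = [_build_motif(spec, rng) for spec, _ in planted]
    planted_total = sum(len(m) for m in motifs)
    n = len(motifs)
    slack = length - planted_total - min_gap * (n + 1)
    if n and slack < 0:
        raise ValueError(
            f"cannot pack {n} plants of total length {planted_total} with "
            f"gaps >= {min_gap} into {length} bases"
        )

    starts: list[int] = []
    if n:
        extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = 0
        for i, motif in enumerate(motifs):
            pos += min_gap + int(extra[i])
            starts.append(pos)
            pos += len(motif)

    intervals = []
    sequences = []
    for (spec, strand), motif, start in zip(planted, motifs, starts):
        if strand not in ("+", "-"):
            raise ValueError("plant strand must be + or -")
        placed = motif if strand == "+" else revcomp(motif)
        intervals.append(
            GenomicInterval(
                chrom=record_id, start=start, end=start + len(motif),
                strand=strand, name=f"plant_{len(intervals)}",
            )
        )
        sequences.append(placed)

    fixed = np.zeros(length, dtype=bool)
    template = np.empty(length, dtype="<U1")
    for iv, placed in zip(intervals, sequences):
        template[iv.start : iv.end] = list(placed)
        fixed[iv.start : iv.end] = True
        for flank in (iv.start - 1, iv.end):
            if 0 <= flank < length:
                template[flank] = rng.choice(_LOOP_BASES)
                fixed[flank] = True

    n_free = int((~fixed).sum())
    for attempt in range(100):
        template[~fixed] = rng.choice(_BASES, size=n_free, p=probs)
        seq = "".join(template)
        record = SequenceRecord(id=record_id, sequence=seq)
        hits = scan_fasta([record], rule, strands="both")
        found = {(h.start, h.end, h.strand) for h in hits}
        truth = {(iv.start, iv.end, iv.strand) for iv in intervals}
        if found == truth:
            return record, PlantedTruth(tuple(intervals), tuple(sequences))
    raise RuntimeError(
        "could not draw a background free of spurious rule matches"
    )


def simulate_annotation(
    n_genes: int,
    genome_length: int,
    seed: int = 0,
    chrom: str = "chr1",
    term_sizes: Sequence[int] = (),
) -> tuple[list[TssRecord], dict[str, set[str]]]:
    """Random gene-level TSS positions plus a GO-style gene-term map.

    TSS positions are uniform without collision, strands Bernoulli(1/2).
    ``term_sizes`` gives the number of genes assigned to each synthetic
    term (GO:SYN0001, GO:SYN0002, ...).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_genes > genome_length / 2000:
        raise ValueError(
            f"cannot place {n_genes} non-overlapping promoters in "
            f"{genome_length} bases"
        )
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(genome_length, size=n_genes, replace=False))
    strands = rng.choice(["+", "-"], size=n_genes)
    tss_records = [
        TssRecord(gene_id=f"gene_{i:04d}", chrom=chrom, tss=int(p), strand=str(s))
        for i, (p, s) in enumerate(zip(positions, strands))
    ]
    gene_ids = [rec.gene_id for rec in tss_records]
    go_map: dict[str, set[str]] = {g: set() for g in gene_ids}
    for t, size in enumerate(term_sizes, start=1):
        if size > n_genes:
            raise ValueError(f"term size {size} exceeds n_genes {n_genes}")
        term = f"GO:SYN{t:04d}"
        for g in rng.choice(gene_ids, size=size, replace=False):
            go_map[str(g)].add(term)
    return tss_records, go_map


# ---------------------------------------------------------------------------
# melting curves and spectra
# ---------------------------------------------------------------------------


def simulate_melt_curve(
    components: Sequence[TwoStateParams],
    t_grid: Sequence[float],
    direction: str = "melt",
    anneal_offset: float = 0.0,
    seed: int = 0,
    series_id: str = "synthetic",
    replicate: int = 1,
) -> MeltCurve:
    """Two-state van't Hoff melting/annealing curve with noise.

    For annealing curves every component's apparent midpoint is shifted
    down by ``anneal_offset`` degC — a phenomenological stand-in for the
    hysteresis caused by folding kinetics being slower than unfolding.
    Component contributions are weighted; weights must sum to 1.
    """
    if direction not in ("melt", "anneal"):
        raise ValueError("direction must be 'melt' or 'anneal'")
    if anneal_offset < 0:
        raise ValueError("anneal_offset must be >= 0")
    t = np.asarray(t_grid, dtype=float)
    if t.min() < 0 or t.max() > 100:
        raise ValueError("temperature grid must lie within [0, 100] degC")
    if np.any(np.diff(np.sort(t)) > 1.0 + 1e-9):
        raise ValueError("temperature grid step must be <= 1 degC")
    weights = [c.weight for c in components]
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("component weights must sum to 1")

    rng = np.random.default_rng(seed)
    absorbance = np.zeros_like(t)
    noise_sd = 0.0
    for comp in components:
        tm_eff = comp.tm - (anneal_offset if direction == "anneal" else 0.0)
        theta = comp.theta(t, tm_eff=tm_eff)
        folded = comp.baseline_folded[0] + comp.baseline_folded[1] * t
        unfolded = comp.baseline_unfolded[0] + comp.baseline_unfolded[1] * t
        absorbance += comp.weight * (folded * theta + unfolded * (1.0 - theta))
        noise_sd += comp.weight * comp.noise_sd
    if noise_sd > 0:
        absorbance = absorbance + rng.normal(0.0, noise_sd, size=t.shape)
    return MeltCurve(
        series_id=series_id,
        direction=direction,
        temperature=t,
        absorbance=absorbance,
        replicate=replicate,
    )


def _gaussian(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def simulate_spectra(
    kind: str,
    seed: int = 0,
    noise_sd: float = 5e-4,
    series_id: str | None = None,
) -> tuple[Spectrum, Spectrum]:
    """A (hot 95 degC, cold 4 degC) absorbance spectrum pair on 220-320 nm.

    For ``i_motif`` the hot-minus-cold difference has its positive extremum
    at 240 nm and its negative extremum at 295 nm (the i-motif TDS
    signature); for ``random_coil`` the difference is non-negative over
    280-320 nm.  Gaussian-band templates on a 1-nm grid plus seeded noise.
    """
    if kind not in ("i_motif", "random_coil"):
        raise ValueError("kind must be 'i_motif' or 'random_coil'")
    rng = np.random.default_rng(seed)
    wl = np.arange(220.0, 321.0, 1.0)
    base = 0.10 + 0.50 * _gaussian(wl, 260.0, 25.0)
    if kind == "i_motif":
        diff = _gaussian(wl, 240.0, 9.0) - 0.55 * _gaussian(wl, 295.0, 8.0)
    else:
        diff = 0.6 * _gaussian(wl, 243.0, 10.0) + _gaussian(wl, 265.0, 12.0)
    amplitude = 0.05
    cold = base + rng.normal(0.0, noise_sd, size=wl.shape)
    hot = base + amplitude * diff + rng.normal(0.0, noise_sd, size=wl.shape)
    sid = series_id or f"synthetic_{kind}"
    return Spectrum(sid, wl, hot), Spectrum(sid, wl, cold)


def simulate_cd_spectrum(
    kind: str,
    seed: int = 0,
    noise_sd: float = 0.05,
    series_id: str | None = None,
) -> Spectrum:
    """A CD scan (200-320 nm, mdeg) of the folded or unfolded state.

    Folded i-motif: +288 nm / -260 nm bands; unfolded: +273 nm / -250 nm.
    """
    if kind not in ("folded", "unfolded"):
        raise ValueError("kind must be 'folded' or 'unfolded'")
    rng = np.random.default_rng(seed)
    wl = np.arange(200.0, 320.5, 0.5)
    if kind == "folded":
        values = 8.0 * _gaussian(wl, 288.0, 8.0) - 5.0 * _gaussian(wl, 260.0, 8.0)
    else:
        values = 5.0 * _gaussian(wl, 273.0, 9.0) - 4.0 * _gaussian(wl, 250.0, 8.0)
    values = values + rng.normal(0.0, noise_sd, size=wl.shape)
    return Spectrum(series_id or f"synthetic_{kind}", wl, values)


def simulate_titration(
    ph_t: float = 7.2,
    slope: float = 2.0,
    e_folded: float = 8.0,
    e_unfolded: float = -1.0,
    ph_grid: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    series_id: str = "synthetic_titration",
) -> TitrationSeries:
    """A sigmoidal ellipticity-vs-pH titration with known pH_T.

    The default grid mirrors the standard experiment: pH 4.0 to 8.0 in
    0.5-unit steps.  Noiseless output passes exactly through
    (e_folded + e_unfolded)/2 at pH_T.
    """
    ph = np.asarray(
        ph_grid if ph_grid is not None else np.arange(4.0, 8.01, 0.5), dtype=float
    )
    if len(ph) < 4:
        raise ValueError("ph_grid needs >= 4 points")
    rng = np.random.default_rng(seed)
    e = titration_model(ph, ph_t, slope, e_folded, e_unfolded)
    if noise_sd > 0:
        e = e + rng.normal(0.0, noise_sd, size=ph.shape)
    return TitrationSeries(series_id=series_id, ph=ph, ellipticity_288=e)
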