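"""Readers and writers for the plain-text formats used across the pipeline.

Conventions shared by every module:

* genomic coordinates are 0-based, half-open, both in memory and in BED
  output; GFF-style 1-based inputs are converted on read;
* sequences are upper-cased on parse (soft-masking is ignored — the screen
  targets sequence content, not repeat status) while the original case is
  kept in ``raw``;
* CSV inputs are comma-separated, UTF-8, ``.`` decimal, header mandatory;
* readers reject malformed input instead of coercing it, and error messages
  name the offending record or row.
"""

from __future__ import annotations

import gzip
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "SequenceRecord",
    "GenomicInterval",
    "CurveTable",
    "Spectrum",
    "read_fasta",
    "write_bed",
    "read_bed",
    "read_curves",
    "read_config",
    "setup_logging",
]

DNA_ALPHABET = frozenset("ACGTN")
STRAND_SYMBOLS = frozenset({"+", "-", "."})


class FormatError(ValueError):
    """An input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet {A, C, G, T, N}.

    ``sequence`` is always upper case; the original (possibly soft-masked)
    spelling is preserved in ``raw``.
    """

    id: str
    sequence: str
    raw: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if not self.raw:
            object.__setattr__(self, "raw", self.sequence)
        seq = self.sequence.upper()
        for pos, ch in enumerate(seq):
            if ch not in DNA_ALPHABET:
                raise FormatError(
                    f"record {self.id!r}: illegal character {ch!r} at position "
                    f"{pos + 1} (alphabet is A/C/G/T/N)"
                )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval, optionally stranded and named."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(
                f"interval {self.name or self.chrom}: negative start {self.start}"
            )
        if self.end <= self.start:
            raise ValueError(
                f"interval {self.name or self.chrom}: end {self.end} must exceed "
                f"start {self.start}"
            )
        if self.strand not in STRAND_SYMBOLS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Spectrum:
    """A wavelength scan (absorbance or ellipticity vs nm)."""

    series_id: str
    wavelength: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.shape != vals.shape or wl.ndim != 1:
            raise ValueError(f"spectrum {self.series_id!r}: shape mismatch")
        order = np.argsort(wl)
        wl, vals = wl[order], vals[order]
        if np.any(np.diff(wl) <= 0):
            raise ValueError(
                f"spectrum {self.series_id!r}: duplicated wavelength values"
            )
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "values", vals)


# canonical curve schemas: input column -> (x, y) mapping per curve kind
_CURVE_SCHEMAS: dict[str, dict[str, str]] = {
    "melt": {"x": "temperature_C", "y": "absorbance"},
    "spectrum": {"x": "wavelength_nm", "y": "value"},
    "cd_titration": {"x": "pH", "y": "ellipticity_288"},
}
_DIRECTIONS = frozenset({"melt", "anneal", "none"})


@dataclass
class CurveTable:
    """Long-form container for curve data.

    ``data`` holds columns (series_id, x, y, direction, replicate), sorted by
    (series_id, direction, replicate, x), with no duplicated keys.  ``kind``
    records which schema the table was read with.
    """

    kind: str
    data: pd.DataFrame

    def series_ids(self) -> list[str]:
        return sorted(self.data["series_id"].unique())

    def iter_series(self) -> Iterator[tuple[tuple[str, str, int], pd.DataFrame]]:
        """Yield ((series_id, direction, replicate), sub-table) groups."""
        for key, grp in self.data.groupby(
            ["series_id", "direction", "replicate"], sort=True
        ):
            yield key, grp.reset_index(drop=True)

    def spectra(self) -> dict[str, Spectrum]:
        """Collapse a ``spectrum`` table into one Spectrum per series."""
        if self.kind != "spectrum":
            raise ValueError(f"not a spectrum table (kind={self.kind!r})")
        out: dict[str, Spectrum] = {}
        for sid, grp in self.data.groupby("series_id", sort=True):
            out[str(sid)] = Spectrum(
                str(sid), grp["x"].to_numpy(), grp["y"].to_numpy()
            )
        return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a (possibly gzipped) multi-record FASTA file.

    Whitespace inside records is stripped by the parser; characters outside
    the A/C/G/T/N alphabet (either case) are rejected with the record name
    and 1-based position.
    """
    with _open_text(path) as handle:
        raw_records = list(SeqIO.parse(handle, "fasta"))
    if not raw_records:
        raise FormatError(f"{path}: no FASTA records found (empty file?)")
    records = []
    for rec in raw_records:
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq), raw=str(rec.seq)))
    return records


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (tab-separated, 0-based half-open)."""
    with open(path, "wt", encoding="utf-8") as out:
        for iv in intervals:
            score = int(iv.score) if float(iv.score).is_integer() else iv.score
            out.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{score}\t{iv.strand}\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED6 file written by :func:`write_bed` (inverse operation)."""
    intervals: list[GenomicInterval] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start, end, name, score, strand = parts[:6]
            try:
                intervals.append(
                    GenomicInterval(
                        chrom=chrom,
                        start=int(start),
                        end=int(end),
                        strand=strand,
                        name="" if name == "." else name,
                        score=float(score),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


# ---------------------------------------------------------------------------
# curve CSVs
# ---------------------------------------------------------------------------


def read_curves(path: str | Path, kind: str) -> CurveTable:
    """Read a curve CSV of the given kind into a canonical CurveTable.

    Kinds and their required columns:

    * ``melt`` — series_id, temperature_C, absorbance, direction, replicate
    * ``spectrum`` — series_id, wavelength_nm, value
    * ``cd_titration`` — series_id, pH, ellipticity_288
    """
    if kind not in _CURVE_SCHEMAS:
        raise ValueError(f"unknown curve kind {kind!r}")
    schema = _CURVE_SCHEMAS[kind]
    required = ["series_id", schema["x"], schema["y"]]
    if kind == "melt":
        required += ["direction", "replicate"]

    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")

    out = pd.DataFrame({"series_id": df["series_id"].astype(str)})
    for canon, col in (("x", schema["x"]), ("y", schema["y"])):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or vals.isna().any():
            row = int(np.flatnonzero(vals.isna())[0])
            raise FormatError(
                f"{path}: non-numeric value in column {col!r} at data row "
                f"{row + 1} ({df[col].iloc[row]!r})"
            )
        out[canon] = vals
    if kind == "melt":
        direction = df["direction"].astype(str).str.strip().str.lower()
        bad_dir = ~direction.isin(_DIRECTIONS)
        if bad_dir.any():
            row = int(np.flatnonzero(bad_dir)[0])
            raise FormatError(
                f"{path}: invalid direction {direction.iloc[row]!r} at data row "
                f"{row + 1} (expected melt/anneal/none)"
            )
        replicate = pd.to_numeric(df["replicate"], errors="coerce")
        if replicate.isna().any():
            row = int(np.flatnonzero(replicate.isna())[0])
            raise FormatError(
                f"{path}: non-numeric replicate at data row {row + 1}"
            )
        out["direction"] = direction
        out["replicate"] = replicate.astype(int)
    else:
        out["direction"] = "none"
        out["replicate"] = 1

    key_cols = ["series_id", "direction", "replicate", "x"]
    dup = out.duplicated(subset=key_cols)
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        raise FormatError(
            f"{path}: duplicated (series, direction, replicate, x) key at data "
            f"row {row + 1}"
        )
    out = out.sort_values(key_cols, kind="mergesort").reset_index(drop=True)
    return CurveTable(kind=kind, data=out[["series_id", "x", "y", "direction", "replicate"]])


# ---------------------------------------------------------------------------
# config + logging
# ---------------------------------------------------------------------------


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a plain-text ``key = value`` configuration file.

    Blank lines and ``#`` comments are ignored.
    """
    config: dict[str, str] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            if "=" not in stripped:
                raise FormatError(f"{path}:{lineno}: expected 'key = value'")
            key, value = stripped.split("=", 1)
            config[key.strip()] = value.strip()
    return config


def setup_logging(level: str = "INFO") -> None:
    """Configure stderr logging for the command-line entry points."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
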