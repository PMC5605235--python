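"""Built-in reference panel of characterized cytosine-rich oligonucleotides.

Two published libraries are bundled as plain-text constants:

* a model library C_n(T_x C_n)_3 — four cytosine tracts of length n
  separated by three thymine loops of length x — with UV melting (Tm),
  annealing (Ta) and transitional pH (pH_T) measurements at pH 5.5 and
  7.4 (plus the human telomeric i-motif hTeloC as a control), and
* 33 genomic i-motif candidate oligonucleotides (23-116 nt, from gene
  promoters and other loci) with Tm/Ta at pH 7.0 and pH_T.

Where a melt showed two transitions both are kept (``tm1`` < ``tm2``);
``largest_tm`` selects the final-unfolding transition used for
stability-vs-loop-length analyses.  Missing measurements (structures that
did not fold under the condition) are NaN.
"""

from __future__ import annotations

import math

import pandas as pd

from .io import SequenceRecord

__all__ = [
    "model_oligos",
    "genomic_oligos",
    "genomic_oligo_records",
    "MODEL_TABLE",
    "GENOMIC_TABLE",
]

_ND = float("nan")


def _model_seq(tract_len: int, loop_len: int) -> str:
    tract = "C" * tract_len
    loop = "T" * loop_len
    return tract + (loop + tract) * 3


# notation, tract_len, loop_len, (pH 5.5: tm1, tm2, ta), (pH 7.4: tm1, tm2, ta), ph_t
# hTeloC is the (TAACCC)x4 human telomeric C-strand control.
MODEL_TABLE: tuple[tuple, ...] = (
    ("hTeloC", None, None, (43.0, _ND, 41.0), (_ND, _ND, _ND), 6.5),
    ("C1T3", 1, 3, (_ND, _ND, _ND), (_ND, _ND, _ND), _ND),
    ("C2T3", 2, 3, (27.1, _ND, 26.2), (_ND, _ND, _ND), 6.1),
    ("C3T3", 3, 3, (46.3, _ND, 45.5), (7.0, _ND, 6.0), 6.7),
    ("C4T3", 4, 3, (56.4, _ND, 55.6), (15.8, _ND, 8.4), 7.1),
    ("C5T3", 5, 3, (61.4, _ND, 60.6), (26.2, _ND, 6.7), 7.2),
    ("C6T3", 6, 3, (65.5, _ND, 63.6), (9.1, 31.3, 9.7), 6.8),
    ("C7T3", 7, 3, (68.5, _ND, 64.7), (12.8, 32.0, 8.7), 7.4),
    ("C8T3", 8, 3, (72.6, _ND, 64.7), (18.8, 35.0, 13.8), 7.1),
    ("C9T3", 9, 3, (75.6, _ND, 65.7), (20.8, 35.0, 12.1), 7.3),
    ("C10T3", 10, 3, (66.0, 77.0, 65.0), (21.9, 41.1, 18.2), 7.3),
    ("C5T1", 5, 1, (60.6, _ND, 59.6), (15.8, _ND, 14.1), 6.9),
    ("C5T2", 5, 2, (60.6, _ND, 60.6), (25.2, _ND, 16.1), 7.1),
    ("C5T4", 5, 4, (63.3, _ND, 60.6), (29.3, _ND, 5.3), 6.7),
)

_HTELOC_SEQ = "TAACCC" * 4

# name, printed sequence (hyphens are cosmetic), tm1, tm2, ta, ph_t at pH 7.0
GENOMIC_TABLE: tuple[tuple[str, str, float, float, float, float], ...] = (
    ("AC017019.1", "CCC-CCC-TCC-CCC-CCT-CCC-CCC-TCC-CCC-C", 27.9, _ND, 18.0, 7.1),
    ("AC018878.3", "CCC-CCA-CCC-CCA-GCC-CCC-TTT-CCC-CC", 18.1, _ND, 7.5, 7.1),
    ("ATXN2L", "CCC-CCC-CCC-CCC-CCC-CCC-CCC-CCC", 23.7, _ND, 22.5, 7.0),
    ("CAMK2G",
     "CCC-CCA-GGC-CCC-GCC-AGT-CCC-CCC-CCC-CGC-CCG-GCC-CCC-GGC-CCG-CCC-CC",
     13.0, _ND, 11.3, 6.9),
    ("DAP", "CCC-CCG-CCC-CCG-CCC-CCG-CCC-CCG-CCC-CC", 24.7, _ND, 22.0, 7.0),
    ("DRP2",
     "CCC-CCT-CTT-CCC-CTC-TCC-CCC-TCT-CCC-CCT-CTC-TCC-CTC-TTC-CCC-CTC-TCC-TTG-"
     "TCT-CCTTCT-CTC-CCC-C",
     4.5, _ND, 6.5, 6.0),
    ("DUX4L22",
     "CCC-CCG-AAA-CGC-GCC-CCC-CTC-CCC-CCT-CCC-CCC-TCT-CCC-CC",
     29.2, _ND, 14.2, 7.1),
    ("GH2",
     "CCC-CCA-CCC-CCA-CCC-CCA-TCC-CCA-CGC-CCC-GCC-CCC-GCC-CCC",
     22.7, _ND, 15.2, 7.1),
    ("HIC2",
     "CCC-CCG-GGA-CAG-GGA-CCC-TGG-CCC-CCC-CCG-ACA-GGC-TGA-CGC-CCA-CCC-CCT-CAA-"
     "ACT-CTG-GTG-GAC-TTA-CCC-CC",
     7.5, _ND, 7.8, 6.4),
    ("HOXC10", "CCC-CCA-CCC-CCA-CCC-CCA-CCC-CCC", 17.7, _ND, 14.0, 7.1),
    ("HOXD10", "CCC-CCC-CCC-CCT-CCC-CCG-CGG-CCC-CC", 10.2, _ND, 5.2, 7.1),
    ("JAZF1", "CCC-CCC-CCG-CCC-CCG-CCC-CCG-CCC-TCC-CCC-C", 20.4, _ND, 18.5, 7.1),
    ("MSMO1", "CCC-CCG-CCC-CCG-CCC-CCG-CCC-CC", 16.6, _ND, 15.9, 6.7),
    ("NFATC1",
     "CCC-CCG-TTT-CCC-CCG-CCA-GCC-CCA-GCG-CCC-CCC-TGC-CCG-GCC-CCC",
     23.2, 28.8, 18.8, 7.1),
    ("PIM1",
     "CCC-CCG-ACG-CGC-CCC-CCA-ACA-CAC-AAA-CCC-CCA-GAA-TCC-GCC-CCC",
     29.4, _ND, 5.1, 7.0),
    ("PLCB2",
     "CCC-CCG-CCT-CTT-CTG-GAG-GCC-CCC-GCC-CCC-ACC-CCC",
     15.0, _ND, 13.2, 7.0),
    ("QSOX1", "CCC-CCG-CCC-CCG-AGC-CCC-CGC-CCC-C", 20.1, _ND, 11.9, 7.1),
    ("RAE1",
     "CCC-CCC-GCC-CCC-CCC-GCC-CCC-CCG-CGC-CGC-CCC-CCC-CCG-CCC-CCC-GCC-CCC-GTC-"
     "CCC-CCG-CCC-CCC-CCG-CCC-CCC-CCG-CCC-CCC-GTC-CCC-CCG-CCC-CCC-CGC-CCC-CCC-"
     "GTC-CCC-CC",
     27.1, _ND, 13.6, 6.8),
    ("RUNX1-1",
     "CCC-CCC-CCG-CAC-CCC-TTC-CCC-CGG-CCC-CCC-C",
     14.3, 25.0, 9.8, 6.7),
    ("RUNX1-2",
     "CCC-CCC-TCC-CCC-TGC-CTC-TCC-CTC-CCC-CCT-TTC-CCC",
     13.2, 24.4, 10.1, 6.5),
    ("RUNX1-3",
     "CCC-CCC-TTT-CCC-CTG-CCC-CCC-CTG-CCT-CCC-CC",
     10.7, 26.2, 9.7, 6.7),
    ("SHANK1b", "CCC-CCC-TCC-CCC-CAC-CCC-CCA-CCC-CCC-C", 22.5, _ND, 12.0, 7.1),
    ("SHANK3",
     "CCC-CCG-CCT-CCG-GCG-CAG-CCC-CCT-CGC-CAC-CCC-CGC-TTC-CCT-CCC-GTC-TCA-GGC-"
     "CCC-CTC-CCC-CCG-CCG-CCC-CCG-CCC-CC",
     18.3, _ND, 5.6, 6.6),
    ("SHANK3b",
     "CCC-CCC-GCA-CCG-AGG-CCT-AGG-ACT-CCC-CCC-CCC-AAC-CCC-GTC-ACA-GCC-CCC-CAG-"
     "ACC-CCC-GCC-CCG-TGG-CTC-GGC-CCC-C",
     12.6, _ND, 4.8, 6.5),
    ("SNORD112",
     "CCC-CCC-CCC-GCC-CCC-CAC-CCC-CCC-ACC-CCC-CCC-CCC",
     25.8, _ND, 15.9, 7.2),
    ("SOX1",
     "CCC-CCT-GCA-GGC-CCC-CCT-GCG-CCT-CCC-CCC-CCC-CGC-CAC-TGG-CGC-CTG-GCT-TCC-CCC",
     9.0, _ND, 6.5, 6.9),
    ("STX17",
     "CCC-CCG-CCC-CCG-CCC-CCG-CCC-CGC-AGG-GCC-CCC",
     19.5, _ND, 15.0, 7.0),
    ("TandemRepeat",
     "CCC-CCC-GTG-TCG-CTG-TTC-CCC-CCG-TGT-CGC-TGT-TCC-CCC-CGT-GTC-GCT-GTT-CCC-CCC",
     9.4, 31.6, 6.7, 6.6),
    ("TRABD", "CCC-CCG-CCC-CCC-CCC-CCC-CCC-CC", 21.3, _ND, 19.3, 6.9),
    ("WNT7A",
     "CCC-CCG-CCC-CTC-CCT-CCT-TTC-CCC-CGT-CCC-TCC-CCC-GCC-CCC-TCC-CCC",
     22.7, _ND, 16.1, 7.1),
    ("ZBTB7B",
     "CCC-CCC-ATC-CCT-CCC-CTC-CCT-CCC-CCC-GCC-CCT-GCC-ACC-CCC-CAA-ACT-CCC-CCC-CCC-C",
     25.5, _ND, 10.0, 7.1),
    ("ZFP41",
     "CCC-CCA-GCC-CCC-GCC-GAC-CCC-CAG-CTC-CCG-CCT-CCG-CCG-ACC-CCC-AGC-CCC-C",
     21.7, 35.6, 17.4, 7.0),
    ("ZNF480", "CCC-CCG-CCC-CCG-CCC-CCG-CCC-CC", 17.1, _ND, 15.2, 6.7),
)


def model_oligos() -> pd.DataFrame:
    """The model C_n T_x library as a tidy DataFrame.

    Columns: notation, sequence, bases, tract_len, loop_len, and per-pH
    measurements tm1/tm2/ta (5.5 and 7.4) plus ph_t.
    """
    rows = []
    for notation, tract_len, loop_len, acid, neutral, ph_t in MODEL_TABLE:
        if notation == "hTeloC":
            seq = _HTELOC_SEQ
        else:
            seq = _model_seq(tract_len, loop_len)
        rows.append(
            {
                "notation": notation,
                "sequence": seq,
                "bases": len(seq),
                "tract_len": tract_len,
                "loop_len": loop_len,
                "tm1_ph55": acid[0],
                "tm2_ph55": acid[1],
                "ta_ph55": acid[2],
                "tm1_ph74": neutral[0],
                "tm2_ph74": neutral[1],
                "ta_ph74": neutral[2],
                "ph_t": ph_t,
            }
        )
    return pd.DataFrame(rows)


def genomic_oligos() -> pd.DataFrame:
    """The 33-sequence genomic candidate panel as a tidy DataFrame.

    Columns: name, sequence, bases, tm1, tm2, largest_tm, ta, ph_t (melts
    at pH 7.0).  ``largest_tm`` is tm2 where a second transition was seen,
    else tm1.
    """
    rows = []
    for name, seq, tm1, tm2, ta, ph_t in GENOMIC_TABLE:
        clean = seq.replace("-", "")
        largest = tm1 if math.isnan(tm2) else tm2
        rows.append(
            {
                "name": name,
                "sequence": clean,
                "bases": len(clean),
                "tm1": tm1,
                "tm2": tm2,
                "largest_tm": largest,
                "ta": ta,
                "ph_t": ph_t,
            }
        )
    return pd.DataFrame(rows)


def genomic_oligo_records() -> list[SequenceRecord]:
    """The genomic panel as SequenceRecord objects."""
    return [
        SequenceRecord(id=name, sequence=seq.replace("-", ""))
        for name, seq, *_ in GENOMIC_TABLE
    ]
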