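"""Packaged count-level fixtures from the apple chilling MSAP study.

The study scored MSAP fragments in four developmental stages — dormant bud
(DB), silver tip (ST), green tip (GT) and initial fruit set (FS) — under
high-chill (H suffix) and low-chill (L suffix) orchard conditions, and
classified low-vs-high-chill banding-pattern changes into the sixteen
comparative classes A-P.  Raw gel scorings were not deposited, so the
fixtures ship at count level: per-sample band-type counts and per-class
comparison counts.  :func:`sample_band_matrix` and
:func:`comparison_band_matrix` expand counts into synthetic band matrices
with exactly those counts, making the published arithmetic reproducible
end-to-end through the matrix-level pipeline; locus identifiers in those
matrices are synthetic (``L0001`` ...), not real fragments.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import pandas as pd

from .core import BandMatrix, LanePresence
from .patterns import PATTERN_BITS
from .stats import ContingencyTable

__all__ = [
    "SAMPLES",
    "COMPARISONS",
    "band_type_counts",
    "pattern_class_counts",
    "band_type_contingency",
    "sample_band_matrix",
    "comparison_band_matrix",
    "ANCHOR_SAMPLE",
]

SAMPLES = ("DBH", "DBL", "STH", "STL", "GTH", "GTL", "FSH", "FSL")
STAGES = ("DB", "ST", "GT", "FS")
COMPARISONS = ("DBL-vs-DBH", "STL-vs-STH", "GTL-vs-GTH", "FSL-vs-FSH")

# Fragments of band types I-IV per sample.
_TYPE_COUNTS: Dict[str, Tuple[int, int, int, int]] = {
    "DBH": (444, 33, 50, 83),
    "DBL": (458, 32, 50, 62),
    "STH": (446, 37, 59, 70),
    "STL": (438, 50, 54, 43),
    "GTH": (466, 30, 62, 59),
    "GTL": (434, 35, 76, 34),
    "FSH": (454, 32, 63, 26),
    "FSL": (410, 49, 52, 29),
}

# Comparative pattern-class counts (classes A-P) per low-vs-high comparison.
_PATTERN_COUNTS: Dict[str, Dict[str, int]] = {
    "DBL-vs-DBH": {
        "A": 432, "B": 23, "C": 44, "D": 62,
        "E": 10, "F": 8, "G": 8, "H": 0, "I": 7, "J": 6,
        "K": 2, "L": 0, "M": 0, "N": 0, "O": 0, "P": 0,
    },
    "STL-vs-STH": {
        "A": 420, "B": 30, "C": 50, "D": 43,
        "E": 2, "F": 6, "G": 10, "H": 2, "I": 11, "J": 3,
        "K": 7, "L": 1, "M": 0, "N": 0, "O": 0, "P": 0,
    },
    "GTL-vs-GTH": {
        "A": 420, "B": 28, "C": 56, "D": 34,
        "E": 0, "F": 8, "G": 6, "H": 0, "I": 5, "J": 8,
        "K": 2, "L": 12, "M": 0, "N": 0, "O": 0, "P": 0,
    },
    "FSL-vs-FSH": {
        "A": 402, "B": 27, "C": 49, "D": 29,
        "E": 0, "F": 2, "G": 6, "H": 1, "I": 4, "J": 2,
        "K": 17, "L": 1, "M": 0, "N": 0, "O": 0, "P": 0,
    },
}

#: Auxiliary all-present sample added when counts are expanded to matrices,
#: so that fully absent loci remain observable (scored type IV / class D).
ANCHOR_SAMPLE = "__anchor__"


def band_type_counts() -> pd.DataFrame:
    """Band-type counts per sample: rows I-IV, one column per sample."""
    return pd.DataFrame(_TYPE_COUNTS, index=["I", "II", "III", "IV"])


def pattern_class_counts() -> pd.DataFrame:
    """Comparative pattern-class counts: rows A-P, one column per comparison."""
    frame = pd.DataFrame(_PATTERN_COUNTS)
    return frame.reindex(sorted(PATTERN_BITS))


def band_type_contingency(stage: str = "pooled") -> ContingencyTable:
    """Band-type x condition contingency table for one stage or pooled.

    Rows are band types I-IV, columns high- vs low-chill; these tables
    feed the chi-square test of chilling-methylation association.
    """
    counts = band_type_counts()
    if stage == "pooled":
        high = counts[[s for s in SAMPLES if s.endswith("H")]].sum(axis=1)
        low = counts[[s for s in SAMPLES if s.endswith("L")]].sum(axis=1)
    elif stage in STAGES:
        high, low = counts[f"{stage}H"], counts[f"{stage}L"]
    else:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES} or 'pooled'")
    return ContingencyTable(
        row_labels=["I", "II", "III", "IV"],
        col_labels=["high_chill", "low_chill"],
        cells=[[int(h), int(l)] for h, l in zip(high, low)],
    )


_TYPE_PRESENCE = {
    "I": LanePresence(hpa=1, msp=1),
    "II": LanePresence(hpa=1, msp=0),
    "III": LanePresence(hpa=0, msp=1),
    "IV": LanePresence(hpa=0, msp=0),
}


def sample_band_matrix(sample: str) -> BandMatrix:
    """Expand one sample's band-type counts into a two-sample band matrix.

    The matrix holds the target sample plus an all-present anchor sample:
    the anchor keeps type-IV loci observable without perturbing the target
    counts.  Scoring the target sample recovers the fixture counts exactly.
    """
    if sample not in _TYPE_COUNTS:
        raise ValueError(f"unknown sample {sample!r}; expected one of {SAMPLES}")
    counts = dict(zip(["I", "II", "III", "IV"], _TYPE_COUNTS[sample]))
    cells: Dict[Tuple[str, str], LanePresence] = {}
    loci: List[str] = []
    i = 0
    for band_type in ("I", "II", "III", "IV"):
        for _ in range(counts[band_type]):
            i += 1
            locus = f"L{i:04d}"
            loci.append(locus)
            cells[(locus, sample)] = _TYPE_PRESENCE[band_type]
            cells[(locus, ANCHOR_SAMPLE)] = LanePresence(1, 1)
    return BandMatrix(
        cells=cells,
        loci=loci,
        samples=[sample, ANCHOR_SAMPLE],
        metadata={"fixture": "band-type counts", "sample": sample},
    )


def comparison_band_matrix(comparison: str) -> BandMatrix:
    """Expand one comparison's class counts into a three-sample matrix.

    Samples are the high-chill control, the low-chill treatment and an
    all-present anchor that keeps class-D loci observable.  Summarizing
    treatment-vs-control recovers the fixture class counts exactly.
    """
    if comparison not in _PATTERN_COUNTS:
        raise ValueError(
            f"unknown comparison {comparison!r}; expected one of {COMPARISONS}"
        )
    treatment, control = comparison.split("-vs-")
    cells: Dict[Tuple[str, str], LanePresence] = {}
    loci: List[str] = []
    i = 0
    for code, n in _PATTERN_COUNTS[comparison].items():
        c_msp, c_hpa, t_msp, t_hpa = PATTERN_BITS[code]
        for _ in range(n):
            i += 1
            locus = f"L{i:04d}"
            loci.append(locus)
            cells[(locus, control)] = LanePresence(c_hpa, c_msp)
            cells[(locus, treatment)] = LanePresence(t_hpa, t_msp)
            cells[(locus, ANCHOR_SAMPLE)] = LanePresence(1, 1)
    return BandMatrix(
        cells=cells,
        loci=loci,
        samples=[control, treatment, ANCHOR_SAMPLE],
        metadata={"fixture": "pattern-class counts", "comparison": comparison},
    )
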