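"""Comparative banding-pattern classification (classes A-P).

Comparing a control and a treatment sample at one locus gives a 4-bit
pattern ``(control_msp, control_hpa, treat_msp, treat_hpa)``.  The sixteen
possible patterns are labelled A-P and partitioned into event groups:

* **no change** (A-D): identical lane pattern in both samples,
* **demethylation** (E-J): bands appear in the treatment relative to the
  control, read as loss of cytosine methylation,
* **methylation** (K-P): bands disappear in the treatment, read as gain.

Bit order is fixed as (MspI, HpaII) within each sample; every interface
documents this to prevent silent transposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

from .core import BandMatrix, BandMatrixError, LanePresence
from .scoring import round_half_up
from .stats import ContingencyTable

__all__ = [
    "GROUPS",
    "PATTERN_BITS",
    "PATTERN_GROUP",
    "PatternClass",
    "ComparisonSummary",
    "classify_pair",
    "summarize_comparison",
    "event_counts_table",
]

GROUPS = ("no_change", "demethylation", "methylation")

# code -> (control_msp, control_hpa, treat_msp, treat_hpa)
PATTERN_BITS: Dict[str, Tuple[int, int, int, int]] = {
    "A": (1, 1, 1, 1),
    "B": (0, 1, 0, 1),
    "C": (1, 0, 1, 0),
    "D": (0, 0, 0, 0),
    "E": (0, 1, 1, 1),
    "F": (1, 0, 1, 1),
    "G": (0, 0, 1, 1),
    "H": (1, 0, 0, 1),
    "I": (0, 0, 0, 1),
    "J": (0, 0, 1, 0),
    "K": (1, 1, 0, 1),
    "L": (1, 1, 1, 0),
    "M": (0, 1, 1, 0),
    "N": (1, 1, 0, 0),
    "O": (0, 1, 0, 0),
    "P": (1, 0, 0, 0),
}

PATTERN_GROUP: Dict[str, str] = {
    **dict.fromkeys("ABCD", "no_change"),
    **dict.fromkeys("EFGHIJ", "demethylation"),
    **dict.fromkeys("KLMNOP", "methylation"),
}

_BITS_TO_CODE = {bits: code for code, bits in PATTERN_BITS.items()}
assert len(_BITS_TO_CODE) == 16


@dataclass(frozen=True)
class PatternClass:
    """One of the 16 comparative banding-pattern classes."""

    code: str
    bits: Tuple[int, int, int, int]
    group: str

    @classmethod
    def from_code(cls, code: str) -> "PatternClass":
        return cls(code, PATTERN_BITS[code], PATTERN_GROUP[code])


def classify_pair(control: LanePresence, treatment: LanePresence) -> PatternClass:
    """Map a (control, treatment) lane-presence pair to its pattern class.

    Total on all 16 bit combinations; a fully absent pair (class D) is only
    meaningful when the locus is observed in some other sample, which is
    the caller's responsibility (see :func:`summarize_comparison`).
    """
    control = LanePresence(*control).validate()
    treatment = LanePresence(*treatment).validate()
    bits = (control.msp, control.hpa, treatment.msp, treatment.hpa)
    return PatternClass.from_code(_BITS_TO_CODE[bits])


@dataclass(frozen=True)
class ComparisonSummary:
    """Per-class and per-group event counts for one control-vs-treatment
    comparison, with group percentages on the comparison total."""

    control_sample: str
    treatment_sample: str
    n_class: Dict[str, int]

    def __post_init__(self) -> None:
        unknown = set(self.n_class) - set(PATTERN_BITS)
        if unknown:
            raise ValueError(f"unknown pattern class codes: {sorted(unknown)}")
        object.__setattr__(
            self, "n_class", {c: int(self.n_class.get(c, 0)) for c in PATTERN_BITS}
        )

    @classmethod
    def from_class_counts(
        cls, control_sample: str, treatment_sample: str, counts: Dict[str, int]
    ) -> "ComparisonSummary":
        return cls(control_sample, treatment_sample, dict(counts))

    @property
    def label(self) -> str:
        return f"{self.treatment_sample}-vs-{self.control_sample}"

    @property
    def n_total(self) -> int:
        return sum(self.n_class.values())

    @property
    def n_group(self) -> Dict[str, int]:
        out = dict.fromkeys(GROUPS, 0)
        for code, n in self.n_class.items():
            out[PATTERN_GROUP[code]] += n
        return out

    @property
    def pct_group(self) -> Dict[str, float]:
        total = self.n_total
        if total == 0:
            raise ZeroDivisionError(f"comparison {self.label} classified no loci")
        return {g: 100.0 * n / total for g, n in self.n_group.items()}

    def pct_group_rounded(self, ndigits: int = 1) -> Dict[str, float]:
        return {g: round_half_up(p, ndigits) for g, p in self.pct_group.items()}


def summarize_comparison(
    matrix: BandMatrix, control_sample: str, treatment_sample: str
) -> ComparisonSummary:
    """Classify every comparable locus of a control/treatment pair.

    The comparison universe is every locus with >=1 band in either member
    of the pair, plus fully absent loci that are observed in some other
    sample of the matrix (those score class D).  Never-observed loci are
    excluded, mirroring the type-IV scoring convention.
    """
    if control_sample == treatment_sample:
        raise BandMatrixError("control and treatment samples must differ")
    for sample in (control_sample, treatment_sample):
        if sample not in matrix.samples:
            raise BandMatrixError(f"unknown sample {sample!r}")
    counts = dict.fromkeys(PATTERN_BITS, 0)
    for locus in matrix.loci:
        control = matrix.presence(locus, control_sample)
        treatment = matrix.presence(locus, treatment_sample)
        if not (control.any_band or treatment.any_band):
            if not matrix.observed_elsewhere(locus, control_sample, treatment_sample):
                continue
        counts[classify_pair(control, treatment).code] += 1
    return ComparisonSummary(control_sample, treatment_sample, counts)


def event_counts_table(
    summaries: Iterable[ComparisonSummary], include_no_change: bool = False
) -> ContingencyTable:
    """Build a group x comparison contingency table of event counts.

    Rows are the demethylation / methylation event groups (plus no-change
    when requested); columns preserve the input comparison order.  The
    result feeds the chi-square test of independence between event type
    and comparison.
    """
    summaries = list(summaries)
    if len(summaries) < 2:
        raise ValueError("need at least two comparisons to build an event table")
    groups = ["demethylation", "methylation"]
    if include_no_change:
        groups = ["no_change"] + groups
    cells = [[s.n_group[g] for s in summaries] for g in groups]
    return ContingencyTable(
        row_labels=groups,
        col_labels=[s.label for s in summaries],
        cells=cells,
    )
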