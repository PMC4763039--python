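"""MSAP band-type scoring (types I-IV) and methylation summary statistics.

Band types follow the standard MSAP reading of the two isoschizomer lanes
at a 5'-CCGG-3' locus:

* **I** — band in both lanes: unmethylated site.
* **II** — band only in the *Eco*RI/*Hpa*II lane: hemi-methylated
  (external cytosine methylated on one strand).
* **III** — band only in the *Eco*RI/*Msp*I lane: fully methylated
  internal cytosine.
* **IV** — band in neither lane, while the fragment is observed in some
  other sample: hyper-methylated (or lost by restriction-site mutation,
  which MSAP cannot distinguish — see the methods note).

A locus that never shows a band in any lane of any sample carries no
information and is excluded from every denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Optional, Sequence

from .core import BandMatrix, BandMatrixError, LanePresence

__all__ = [
    "BandType",
    "MethylationSummary",
    "classify_locus_sample",
    "summarize_sample",
    "pool_summaries",
    "round_half_up",
]


class BandType(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as tabulated percentages are printed."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def classify_locus_sample(
    presence: LanePresence, observed_elsewhere: bool
) -> Optional[BandType]:
    """Classify one locus in one sample into a band type.

    ``observed_elsewhere`` must be True iff the locus has at least one band
    in any lane of any *other* sample: a (0, 0) pattern is type IV only
    relative to samples where the fragment exists.  Returns ``None`` for a
    never-observed locus (excluded from scoring).
    """
    presence = LanePresence(*presence).validate()
    if presence.hpa and presence.msp:
        return BandType.I
    if presence.hpa:
        return BandType.II
    if presence.msp:
        return BandType.III
    return BandType.IV if observed_elsewhere else None


@dataclass(frozen=True)
class MethylationSummary:
    """Band-type counts for one sample (or a pooled condition) with the
    derived methylation percentages.

    Percentages are carried at full precision; use :meth:`rounded` for the
    1-decimal rendering used in reports.
    """

    label: str
    n_I: int
    n_II: int
    n_III: int
    n_IV: int

    def __post_init__(self) -> None:
        for name in ("n_I", "n_II", "n_III", "n_IV"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_counts(cls, label: str, counts: Sequence[int]) -> "MethylationSummary":
        """Build from a (type I, II, III, IV) count vector."""
        n1, n2, n3, n4 = counts
        return cls(label, int(n1), int(n2), int(n3), int(n4))

    @property
    def n_total(self) -> int:
        return self.n_I + self.n_II + self.n_III + self.n_IV

    def count(self, band_type: BandType) -> int:
        return {
            BandType.I: self.n_I,
            BandType.II: self.n_II,
            BandType.III: self.n_III,
            BandType.IV: self.n_IV,
        }[band_type]

    def _pct(self, numerator: int) -> float:
        if self.n_total == 0:
            raise ZeroDivisionError(
                f"summary {self.label!r} has no scored fragments"
            )
        return 100.0 * numerator / self.n_total

    @property
    def pct_total_methylation(self) -> float:
        """Percent of scored fragments showing any methylation (II+III+IV)."""
        return self._pct(self.n_II + self.n_III + self.n_IV)

    @property
    def pct_fully_methylated(self) -> float:
        """Percent fully methylated (III) plus hyper-methylated (IV)."""
        return self._pct(self.n_III + self.n_IV)

    @property
    def pct_hemi_methylated(self) -> float:
        """Percent hemi-methylated (type II)."""
        return self._pct(self.n_II)

    def rounded(self, ndigits: int = 1) -> dict:
        """Percentages rounded half-up, as printed in summary tables."""
        return {
            "pct_total_methylation": round_half_up(self.pct_total_methylation, ndigits),
            "pct_fully_methylated": round_half_up(self.pct_fully_methylated, ndigits),
            "pct_hemi_methylated": round_half_up(self.pct_hemi_methylated, ndigits),
        }


def summarize_sample(matrix: BandMatrix, sample: str) -> MethylationSummary:
    """Score every non-excluded locus of ``sample`` and tally band types."""
    if sample not in matrix.samples:
        raise BandMatrixError(f"unknown sample {sample!r}")
    counts = {bt: 0 for bt in BandType}
    for locus in matrix.loci:
        presence = matrix.presence(locus, sample)
        band_type = classify_locus_sample(
            presence, matrix.observed_elsewhere(locus, sample)
        )
        if band_type is not None:
            counts[band_type] += 1
    return MethylationSummary(
        sample, counts[BandType.I], counts[BandType.II], counts[BandType.III], counts[BandType.IV]
    )


def pool_summaries(
    summaries: Iterable[MethylationSummary], label: str
) -> MethylationSummary:
    """Pool summaries by summing type counts; percentages are recomputed
    from the pooled counts, never averaged."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("cannot pool an empty list of summaries")
    return MethylationSummary(
        label,
        sum(s.n_I for s in summaries),
        sum(s.n_II for s in summaries),
        sum(s.n_III for s in summaries),
        sum(s.n_IV for s in summaries),
    )
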