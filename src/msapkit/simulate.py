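"""Forward simulation of the MSAP assay and bisulfite conversion.

The simulator is the known-truth test bed for the pipeline: it draws a
methylation state per 5'-CCGG-3' locus and sample, converts the state to
lane presence via the isoschizomer sensitivity rules, optionally flips
bits to emulate scoring noise, and (separately) emits bisulfite-converted
clone sequences from a random reference with per-context methylation
probabilities and a conversion-efficiency parameter.

Isoschizomer sensitivity at CCGG:

* *Hpa*II cuts unmethylated and hemi-methylated sites but is blocked by
  full (double-strand) methylation.
* *Msp*I cuts when the internal cytosine is methylated (C5mCGG, hemi or
  full) but is blocked by external-cytosine methylation (5mCCGG).

This gives the digestion truth table in :func:`digestion_pattern`.  Note
the assay's blind spot: a hemi-methylated internal cytosine (``HM_INT``)
is cut by both enzymes and is indistinguishable from unmethylated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bisulfite import CytosineContext, classify_cytosine_contexts
from .core import BandMatrix, LanePresence

__all__ = [
    "MethylationState",
    "SimulationConfig",
    "BisulfiteSimConfig",
    "MsapTruth",
    "BisulfiteTruth",
    "digestion_pattern",
    "simulate_msap",
    "simulate_bisulfite",
]


class MethylationState(str, Enum):
    """Methylation state of a CCGG site.

    U: unmethylated; HM_EXT: external C methylated on one strand;
    HM_INT: internal C methylated on one strand; FM_INT: internal C
    methylated on both strands; X: external (or both) Cs methylated on
    both strands (hyper-methylated, no band in either lane).
    """

    U = "U"
    HM_EXT = "HM_ext"
    HM_INT = "HM_int"
    FM_INT = "FM_int"
    X = "X"


_DIGESTION: Dict[MethylationState, LanePresence] = {
    MethylationState.U: LanePresence(hpa=1, msp=1),
    MethylationState.HM_EXT: LanePresence(hpa=1, msp=0),
    MethylationState.HM_INT: LanePresence(hpa=1, msp=1),
    MethylationState.FM_INT: LanePresence(hpa=0, msp=1),
    MethylationState.X: LanePresence(hpa=0, msp=0),
}


def digestion_pattern(state: MethylationState) -> LanePresence:
    """Lane presence produced by a CCGG site in the given state."""
    return _DIGESTION[MethylationState(state)]


STATE_ORDER = (
    MethylationState.U,
    MethylationState.HM_EXT,
    MethylationState.HM_INT,
    MethylationState.FM_INT,
    MethylationState.X,
)


def _check_probs(probs: Sequence[float], what: str, must_sum: bool = True) -> np.ndarray:
    arr = np.asarray(probs, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"{what}: probabilities must lie in [0, 1], got {list(arr)}")
    if must_sum and abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"{what}: probabilities must sum to 1, got {arr.sum()!r}")
    return arr


@dataclass
class BisulfiteSimConfig:
    """Parameters of the bisulfite-conversion simulation.

    ``context_probs`` gives the probability that a cytosine of each
    determined context is methylated; ``conversion_efficiency`` is the
    probability that an unmethylated C reads as T (incomplete conversion
    leaves residual Cs that inflate apparent methylation).
    """

    locus_length: int = 300
    gc_content: float = 0.45
    context_probs: Dict[str, float] = field(
        default_factory=lambda: {"CG": 0.8, "CHG": 0.3, "CHH": 0.05}
    )
    conversion_efficiency: float = 1.0
    clones_per_sample: int = 1

    def validate(self) -> "BisulfiteSimConfig":
        if self.locus_length < 3:
            raise ValueError("locus_length must be >= 3")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        for ctx in ("CG", "CHG", "CHH"):
            if ctx not in self.context_probs:
                raise ValueError(f"context_probs missing context {ctx!r}")
        _check_probs(list(self.context_probs.values()), "context_probs", must_sum=False)
        _check_probs([self.conversion_efficiency], "conversion_efficiency", must_sum=False)
        if self.clones_per_sample < 1:
            raise ValueError("clones_per_sample must be >= 1")
        return self


@dataclass
class SimulationConfig:
    """Full simulation configuration.

    ``state_probs`` maps each sample to a probability vector over the five
    CCGG methylation states in :data:`STATE_ORDER`; ``band_noise`` is the
    per-lane probability of flipping an emitted presence bit.  One integer
    seed governs all randomness; per-locus/sample sub-streams are derived
    deterministically so adding samples does not perturb existing draws.
    """

    n_loci: int
    samples: List[str]
    state_probs: Dict[str, Sequence[float]]
    band_noise: float = 0.0
    seed: int = 0
    bisulfite: Optional[BisulfiteSimConfig] = None

    def validate(self) -> "SimulationConfig":
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not self.samples:
            raise ValueError("at least one sample is required")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers must be unique")
        for sample in self.samples:
            if sample not in self.state_probs:
                raise ValueError(f"state_probs missing sample {sample!r}")
            probs = self.state_probs[sample]
            if len(probs) != len(STATE_ORDER):
                raise ValueError(
                    f"state_probs[{sample!r}] must have {len(STATE_ORDER)} entries "
                    f"(order {[s.value for s in STATE_ORDER]})"
                )
            _check_probs(probs, f"state_probs[{sample!r}]")
        _check_probs([self.band_noise], "band_noise", must_sum=False)
        if self.bisulfite is not None:
            self.bisulfite.validate()
        return self


@dataclass
class MsapTruth:
    """Ground-truth methylation state per (locus, sample)."""

    states: Dict[Tuple[str, str], MethylationState]

    def state_counts(self, sample: str) -> Dict[MethylationState, int]:
        counts = {s: 0 for s in STATE_ORDER}
        for (_, smp), state in self.states.items():
            if smp == sample:
                counts[state] += 1
        return counts


@dataclass
class BisulfiteTruth:
    """Ground truth for the bisulfite simulation: a methylated flag per
    (sample, classifiable cytosine position), plus each position's context."""

    flags: Dict[Tuple[str, int], bool]
    contexts: Dict[int, CytosineContext]

    def positions(self) -> List[int]:
        return sorted(
            p for p, c in self.contexts.items() if c is not CytosineContext.UNDETERMINED
        )


def _substream(seed: int, *tokens: str) -> np.random.Generator:
    """Deterministic per-entity random stream, stable under reordering."""
    keys = [zlib.crc32(t.encode("utf-8")) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, *keys]))


def simulate_msap(config: SimulationConfig) -> Tuple[BandMatrix, MsapTruth]:
    """Draw states, apply digestion rules and scoring noise; return the
    observed band matrix with its truth table."""
    config.validate()
    loci = [f"L{i + 1:05d}" for i in range(config.n_loci)]
    cells: Dict[Tuple[str, str], LanePresence] = {}
    states: Dict[Tuple[str, str], MethylationState] = {}
    for locus in loci:
        for sample in config.samples:
            rng = _substream(config.seed, "msap", locus, sample)
            probs = np.asarray(config.state_probs[sample], dtype=float)
            state = STATE_ORDER[rng.choice(len(STATE_ORDER), p=probs / probs.sum())]
            states[(locus, sample)] = state
            hpa, msp = digestion_pattern(state)
            if config.band_noise > 0:
                if rng.random() < config.band_noise:
                    hpa = 1 - hpa
                if rng.random() < config.band_noise:
                    msp = 1 - msp
            cells[(locus, sample)] = LanePresence(hpa, msp)
    matrix = BandMatrix(
        cells=cells,
        loci=loci,
        samples=list(config.samples),
        metadata={"simulated": "true", "seed": str(config.seed)},
    )
    return matrix, MsapTruth(states)


def _random_reference(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def simulate_bisulfite(
    config: SimulationConfig,
) -> Tuple[str, Dict[str, List[str]], BisulfiteTruth]:
    """Simulate one locus: a random reference, per-sample bisulfite clones,
    and the truth table of methylated cytosines.

    Methylation flags are drawn per (sample, cytosine) with the context's
    probability; all clones of a sample share its flags (the sequenced
    amplicon re-reads one molecule population), while conversion failures
    are drawn independently per clone and position.  Returns
    ``(reference, {sample: [clone, ...]}, truth)``.
    """
    config.validate()
    if config.bisulfite is None:
        raise ValueError("config.bisulfite block is required")
    bs = config.bisulfite
    ref_rng = _substream(config.seed, "bisulfite", "reference")
    reference = _random_reference(ref_rng, bs.locus_length, bs.gc_content)
    contexts = dict(classify_cytosine_contexts(reference))
    classifiable = [
        (p, c) for p, c in sorted(contexts.items())
        if c is not CytosineContext.UNDETERMINED
    ]
    flags: Dict[Tuple[str, int], bool] = {}
    clones: Dict[str, List[str]] = {}
    for sample in config.samples:
        state_rng = _substream(config.seed, "bisulfite", "state", sample)
        for position, context in classifiable:
            flags[(sample, position)] = bool(
                state_rng.random() < bs.context_probs[context.value]
            )
        clones[sample] = []
        for clone_idx in range(bs.clones_per_sample):
            rng = _substream(config.seed, "bisulfite", "clone", sample, str(clone_idx))
            seq = list(reference)
            for position in range(len(seq)):
                if seq[position] != "C":
                    continue
                if flags.get((sample, position), False):
                    continue  # methylated Cs resist conversion
                if rng.random() < bs.conversion_efficiency:
                    seq[position] = "T"
            clones[sample].append("".join(seq))
    truth = BisulfiteTruth(flags, {p: c for p, c in contexts.items()})
    return reference, clones, truth
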