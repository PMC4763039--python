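"""Cytosine-context classification and bisulfite methylation calling.

Bisulfite treatment converts unmethylated cytosines to uracil (read as T
after PCR) while methylated cytosines stay C.  Comparing a clone sequence
from bisulfite-converted DNA against the unconverted reference therefore
calls each reference cytosine methylated (C -> C) or unmethylated
(C -> T); any other clone base is ambiguous (sequencing error or SNP) and
is excluded from percentages.

Contexts are the standard plant trinucleotide classes on the top strand:
CG, CHG and CHH, where H is A, C or T.  A cytosine too close to the
sequence end (or with an intervening N) to decide is ``undetermined`` and
excluded from numerator and denominator alike.

Analysis is top-strand only and gap-free: clones are cloned PCR amplicons
of a fixed locus, pre-aligned to the reference at equal length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Tuple, Union

from Bio import SeqIO

__all__ = [
    "CytosineContext",
    "MethylationState",
    "CytosineCall",
    "BisulfiteSummary",
    "classify_cytosine_contexts",
    "call_methylation",
    "methylation_percentage",
    "read_locus_fasta",
]

_ALPHABET = set("ACGTN")
_H = set("ACT")


class CytosineContext(str, Enum):
    CG = "CG"
    CHG = "CHG"
    CHH = "CHH"
    UNDETERMINED = "undetermined"


class MethylationState(str, Enum):
    METHYLATED = "methylated"
    UNMETHYLATED = "unmethylated"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class CytosineCall:
    """Methylation call for one reference cytosine (0-based position)."""

    position: int
    context: CytosineContext
    state: MethylationState


def _check_alphabet(sequence: str, name: str) -> str:
    sequence = sequence.upper()
    for i, base in enumerate(sequence):
        if base not in _ALPHABET:
            raise ValueError(
                f"{name} contains invalid character {base!r} at position {i}"
            )
    return sequence


def classify_cytosine_contexts(
    reference: str,
) -> List[Tuple[int, CytosineContext]]:
    """Classify every top-strand cytosine of ``reference``.

    For a C at position i: CG when base i+1 is G; CHG when base i+1 is H
    and base i+2 is G; CHH when bases i+1 and i+2 are both H; undetermined
    when the required downstream bases run off the sequence end or an N
    intervenes.
    """
    reference = _check_alphabet(str(reference), "reference")
    out: List[Tuple[int, CytosineContext]] = []
    n = len(reference)
    for i, base in enumerate(reference):
        if base != "C":
            continue
        nxt = reference[i + 1] if i + 1 < n else None
        nxt2 = reference[i + 2] if i + 2 < n else None
        if nxt == "G":
            context = CytosineContext.CG
        elif nxt in _H and nxt2 == "G":
            context = CytosineContext.CHG
        elif nxt in _H and nxt2 in _H:
            context = CytosineContext.CHH
        else:
            context = CytosineContext.UNDETERMINED
        out.append((i, context))
    return out


def call_methylation(reference: str, clone: str) -> List[CytosineCall]:
    """Call methylation of each reference C from one bisulfite clone.

    Requires gap-free, equal-length sequences.  C -> C is methylated,
    C -> T unmethylated, any other clone base ambiguous.
    """
    reference = _check_alphabet(str(reference), "reference")
    clone = _check_alphabet(str(clone), "clone")
    if len(reference) != len(clone):
        raise ValueError(
            f"reference ({len(reference)} nt) and clone ({len(clone)} nt) "
            "must be pre-aligned to equal length"
        )
    contexts = dict(classify_cytosine_contexts(reference))
    calls = []
    for position, context in sorted(contexts.items()):
        base = clone[position]
        if base == "C":
            state = MethylationState.METHYLATED
        elif base == "T":
            state = MethylationState.UNMETHYLATED
        else:
            state = MethylationState.AMBIGUOUS
        calls.append(CytosineCall(position, context, state))
    return calls


@dataclass(frozen=True)
class BisulfiteSummary:
    """Methylated / countable cytosine tallies, overall and per context.

    Countable cytosines are those with a determined context and an
    unambiguous call; ``n_undetermined`` and ``n_ambiguous`` report what
    was excluded.  Percentages follow
    ``100 * methylated / total`` within each stratum.
    """

    n_methylated: Dict[str, int]
    n_total: Dict[str, int]
    n_undetermined: int
    n_ambiguous: int

    @property
    def overall_methylated(self) -> int:
        return sum(self.n_methylated.values())

    @property
    def overall_total(self) -> int:
        return sum(self.n_total.values())

    @property
    def pct_methylated(self) -> float:
        return 100.0 * self.overall_methylated / self.overall_total

    def pct_by_context(self) -> Dict[str, float]:
        out = {}
        for context, total in self.n_total.items():
            if total:
                out[context] = 100.0 * self.n_methylated[context] / total
        return out


def methylation_percentage(
    calls: Iterable[CytosineCall], stratify: bool = True
) -> BisulfiteSummary:
    """Summarize calls into per-context and overall methylation percentages.

    When several clones of one locus are supplied, concatenate their calls:
    cytosines are counted per clone-position occurrence.  Raises when no
    countable cytosine remains (the percentage would be 0/0).
    """
    contexts = [CytosineContext.CG, CytosineContext.CHG, CytosineContext.CHH]
    n_methylated = {c.value: 0 for c in contexts}
    n_total = {c.value: 0 for c in contexts}
    n_undetermined = 0
    n_ambiguous = 0
    for call in calls:
        if call.context is CytosineContext.UNDETERMINED:
            n_undetermined += 1
            continue
        if call.state is MethylationState.AMBIGUOUS:
            n_ambiguous += 1
            continue
        n_total[call.context.value] += 1
        if call.state is MethylationState.METHYLATED:
            n_methylated[call.context.value] += 1
    summary = BisulfiteSummary(n_methylated, n_total, n_undetermined, n_ambiguous)
    if summary.overall_total == 0:
        raise ZeroDivisionError("no countable cytosines (determined context, unambiguous call)")
    if not stratify:
        total = summary.overall_total
        meth = summary.overall_methylated
        summary = BisulfiteSummary(
            {"all": meth}, {"all": total}, n_undetermined, n_ambiguous
        )
    return summary


def read_locus_fasta(path: str) -> Dict[str, Dict[str, List[str]]]:
    """Read a per-locus FASTA of reference plus clone records.

    Record ids follow ``locus|sample|clone``; the reference record for a
    locus uses the sample field ``ref`` (e.g. ``locusA|ref|0``) or a bare
    ``locus`` id.  Returns ``{locus: {"ref": [seq], sample: [clone seqs]}}``.
    """
    out: Dict[str, Dict[str, List[str]]] = {}
    for record in SeqIO.parse(path, "fasta"):
        parts = record.id.split("|")
        locus = parts[0]
        sample = parts[1] if len(parts) > 1 else "ref"
        out.setdefault(locus, {}).setdefault(sample, []).append(str(record.seq).upper())
    return out
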