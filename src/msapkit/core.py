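"""Core domain types and I/O for MSAP band-observation matrices.

An MSAP (methylation-sensitive amplified polymorphism) experiment digests
genomic DNA with *Eco*RI plus one of the isoschizomers *Hpa*II / *Msp*I and
scores, for every amplified fragment (locus) in every sample, whether a band
is visible in each enzyme lane.  The central observation table here is the
:class:`BandMatrix`: one presence bit per (locus, sample, lane).

The canonical on-disk representation is a long (tidy) tab-separated file::

    locus_id  sample_id  hpaii  mspi
    L001      DBH        1      1

A wide dialect (one row per locus, a ``<sample>.hpaii`` / ``<sample>.mspi``
column pair per sample) is accepted on read only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, TextIO, Union

__all__ = [
    "LanePresence",
    "BandMatrix",
    "SampleLabel",
    "Finding",
    "BandMatrixError",
    "parse_sample_label",
    "read_band_matrix",
    "write_band_matrix",
    "validate_band_matrix",
]

LONG_HEADER = ("locus_id", "sample_id", "hpaii", "mspi")

STAGES = ("DB", "ST", "GT", "FS")
CONDITIONS = ("high_chill", "low_chill")


class BandMatrixError(ValueError):
    """Raised on malformed band-matrix input or invalid matrix access."""


class LanePresence(NamedTuple):
    """Band presence bits for one locus in one sample.

    ``hpa`` is 1 when the fragment band is present in the *Eco*RI/*Hpa*II
    lane, ``msp`` when present in the *Eco*RI/*Msp*I lane.
    """

    hpa: int
    msp: int

    def validate(self) -> "LanePresence":
        for name, bit in (("hpa", self.hpa), ("msp", self.msp)):
            if bit not in (0, 1):
                raise BandMatrixError(
                    f"lane presence bit {name!r} must be 0 or 1, got {bit!r}"
                )
        return self

    @property
    def any_band(self) -> bool:
        return bool(self.hpa or self.msp)


@dataclass(frozen=True)
class SampleLabel:
    """Parsed developmental stage and chilling condition of a sample.

    Stages: dormant bud (DB), silver tip (ST), green tip (GT), initial
    fruit set (FS).  The condition encodes the chilling availability of the
    sampling site (high vs low chill).
    """

    stage: str
    condition: str

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )


_LABEL_RE = re.compile(r"^(DB|ST|GT|FS)([HL])$")


def parse_sample_label(sample_id: str) -> SampleLabel:
    """Parse a sample identifier like ``DBH`` or ``FSL``.

    The suffix convention is ``H`` = high chill, ``L`` = low chill; the
    prefix is the developmental stage.  Raises ``ValueError`` when the
    identifier does not follow the convention (sample ids are otherwise
    free strings at the I/O layer).
    """
    m = _LABEL_RE.match(sample_id.strip())
    if m is None:
        raise ValueError(
            f"sample id {sample_id!r} does not follow the <stage><H|L> convention"
        )
    stage, chill = m.groups()
    return SampleLabel(stage, "high_chill" if chill == "H" else "low_chill")


@dataclass
class BandMatrix:
    """Per-locus, per-sample band presence observations.

    ``loci`` and ``samples`` are ordered and unique; ``cells`` maps every
    (locus, sample) pair to a :class:`LanePresence`.  A missing cell is a
    validation finding, never an implicit (0, 0): absence from both lanes
    is itself a scored datum.
    """

    cells: dict
    loci: list = field(default_factory=list)
    samples: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.loci:
            seen = dict.fromkeys(locus for locus, _ in self.cells)
            self.loci = list(seen)
        if not self.samples:
            seen = dict.fromkeys(sample for _, sample in self.cells)
            self.samples = list(seen)
        if len(set(self.loci)) != len(self.loci):
            raise BandMatrixError("duplicate locus identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise BandMatrixError("duplicate sample identifiers")
        for key, presence in self.cells.items():
            locus, sample = key
            if locus not in set(self.loci) or sample not in set(self.samples):
                raise BandMatrixError(f"cell {key!r} outside declared loci/samples")
            LanePresence(*presence).validate()

    def presence(self, locus: str, sample: str) -> LanePresence:
        try:
            return LanePresence(*self.cells[(locus, sample)])
        except KeyError:
            raise BandMatrixError(f"missing cell for locus {locus!r}, sample {sample!r}")

    def observed_anywhere(self, locus: str) -> bool:
        """True when the locus shows >=1 band in any lane of any sample."""
        return any(
            self.presence(locus, s).any_band
            for s in self.samples
            if (locus, s) in self.cells
        )

    def observed_elsewhere(self, locus: str, *exclude: str) -> bool:
        """True when the locus shows >=1 band in a sample not in ``exclude``."""
        skip = set(exclude)
        return any(
            self.presence(locus, s).any_band
            for s in self.samples
            if s not in skip and (locus, s) in self.cells
        )

    def require_complete(self) -> None:
        missing = [
            (locus, sample)
            for locus in self.loci
            for sample in self.samples
            if (locus, sample) not in self.cells
        ]
        if missing:
            raise BandMatrixError(
                f"band matrix is incomplete: {len(missing)} missing cell(s), "
                f"first {missing[0]!r}"
            )


@dataclass(frozen=True)
class Finding:
    """One validation finding; validation reports, it never repairs."""

    code: str
    message: str


def validate_band_matrix(matrix: BandMatrix) -> list:
    """Check matrix invariants, returning one :class:`Finding` per violation.

    Checks: every (locus, sample) cell present; presence bits in {0, 1};
    loci that are (0, 0) in every sample (unobservable — they can never be
    scored and would silently shrink denominators).
    """
    findings = []
    for locus in matrix.loci:
        for sample in matrix.samples:
            if (locus, sample) not in matrix.cells:
                findings.append(
                    Finding("missing cell", f"no observation for ({locus!r}, {sample!r})")
                )
    for key, presence in matrix.cells.items():
        hpa, msp = presence
        if hpa not in (0, 1) or msp not in (0, 1):
            findings.append(
                Finding("invalid bit", f"cell {key!r} has non-binary presence {presence!r}")
            )
    for locus in matrix.loci:
        observed = any(
            matrix.cells[(locus, s)][0] or matrix.cells[(locus, s)][1]
            for s in matrix.samples
            if (locus, s) in matrix.cells
        )
        if not observed:
            findings.append(
                Finding(
                    "unobservable locus",
                    f"locus {locus!r} has no band in any lane of any sample",
                )
            )
    return findings


def _open_text(source: Union[str, TextIO], mode: str):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode, encoding="utf-8", newline=""), True


def read_band_matrix(source: Union[str, TextIO], dialect: str = "long") -> BandMatrix:
    """Read a band matrix from tab-separated text.

    ``dialect`` is ``"long"`` (canonical; header ``locus_id sample_id hpaii
    mspi``) or ``"wide"`` (one row per locus with ``<sample>.hpaii`` /
    ``<sample>.mspi`` column pairs; read-only convenience).  Duplicate
    (locus, sample) rows, presence values outside {0, 1} and ragged rows
    are hard errors.
    """
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}")
    handle, close = _open_text(source, "r")
    try:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in handle]
    finally:
        if close:
            handle.close()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise BandMatrixError("empty band matrix file (missing header)")
    header = tuple(lines[0].split("\t"))
    if dialect == "long":
        return _read_long(header, lines[1:])
    return _read_wide(header, lines[1:])


def _parse_bit(token: str, line_no: int) -> int:
    if token not in ("0", "1"):
        raise BandMatrixError(
            f"line {line_no}: value outside {{0,1}}: {token!r}"
        )
    return int(token)


def _read_long(header, rows) -> BandMatrix:
    if header != LONG_HEADER:
        raise BandMatrixError(
            f"expected header {list(LONG_HEADER)}, got {list(header)}"
        )
    cells: dict = {}
    loci: dict = {}
    samples: dict = {}
    for i, line in enumerate(rows, start=2):
        parts = line.split("\t")
        if len(parts) != 4:
            raise BandMatrixError(f"line {i}: ragged row with {len(parts)} fields")
        locus, sample, hpa_tok, msp_tok = parts
        key = (locus, sample)
        if key in cells:
            raise BandMatrixError(
                f"line {i}: duplicate row for locus {locus!r}, sample {sample!r}"
            )
        cells[key] = LanePresence(_parse_bit(hpa_tok, i), _parse_bit(msp_tok, i))
        loci[locus] = None
        samples[sample] = None
    return BandMatrix(cells=cells, loci=list(loci), samples=list(samples))


def _read_wide(header, rows) -> BandMatrix:
    if not header or header[0] != "locus_id":
        raise BandMatrixError("wide dialect must start with a 'locus_id' column")
    lane_cols = header[1:]
    if len(lane_cols) % 2:
        raise BandMatrixError("wide dialect needs an hpaii/mspi column pair per sample")
    samples = []
    for j in range(0, len(lane_cols), 2):
        a, b = lane_cols[j], lane_cols[j + 1]
        if not (a.endswith(".hpaii") and b.endswith(".mspi")):
            raise BandMatrixError(f"expected '<sample>.hpaii'/'<sample>.mspi' pair, got {a!r}, {b!r}")
        sa, sb = a[: -len(".hpaii")], b[: -len(".mspi")]
        if sa != sb:
            raise BandMatrixError(f"mismatched sample names in column pair {a!r}, {b!r}")
        samples.append(sa)
    if len(set(samples)) != len(samples):
        raise BandMatrixError("duplicate sample columns in wide header")
    cells: dict = {}
    loci: dict = {}
    for i, line in enumerate(rows, start=2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise BandMatrixError(f"line {i}: ragged row with {len(parts)} fields")
        locus = parts[0]
        if locus in loci:
            raise BandMatrixError(f"line {i}: duplicate locus {locus!r}")
        loci[locus] = None
        for j, sample in enumerate(samples):
            hpa = _parse_bit(parts[1 + 2 * j], i)
            msp = _parse_bit(parts[2 + 2 * j], i)
            cells[(locus, sample)] = LanePresence(hpa, msp)
    return BandMatrix(cells=cells, loci=list(loci), samples=samples)


def write_band_matrix(matrix: BandMatrix, sink: Union[str, TextIO]) -> None:
    """Write the long dialect, header first, rows sorted by (locus, sample)."""
    handle, close = _open_text(sink, "w")
    try:
        handle.write("\t".join(LONG_HEADER) + "\n")
        for locus, sample in sorted(matrix.cells):
            p = matrix.presence(locus, sample)
            handle.write(f"{locus}\t{sample}\t{p.hpa}\t{p.msp}\n")
    finally:
        if close:
            handle.close()
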