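"""Reading and writing aligned sequence sets and PWM tables.

Three input dialects are supported:

``plain``
    One sequence per line, already center-aligned; all lines must have
    equal length.
``fasta``
    Standard FASTA; records may differ in length and are center-aligned
    across the entire record (flanks on either side of any consensus
    are assumed equal).
``jaspar``
    FASTA in the style of JASPAR motif downloads: the consensus motif is
    UPPERCASE, flanking sequence lowercase.  Records are aligned on the
    centers of their uppercase runs and flanks trimmed to the largest
    width common to all records.

Gap characters (``-`` and ``.``) are stripped before alignment; any
other non-ACGT character becomes ``N`` and is masked out of frequency
counts downstream.  Positions are 1-based; linkage *j* sits between
bases *j* and *j+1*.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import DialectError, EmptyInputError, FormatError, ValidationError

__all__ = [
    "SequenceSet",
    "read_plain",
    "read_fasta",
    "read_jaspar_fasta",
    "read_sequences",
    "write_plain",
    "write_fasta",
    "write_jaspar_fasta",
    "write_pwm",
    "read_pwm",
]

_GAPS = str.maketrans("", "", "-.")
_VALID = set("ACGTN")


def _clean(seq: str) -> str:
    """Strip gaps, uppercase, and map non-ACGT characters to N."""
    s = seq.translate(_GAPS).upper()
    return "".join(c if c in "ACGT" else "N" for c in s)


@dataclass(frozen=True)
class SequenceSet:
    """An equal-length, center-aligned set of DNA sequences.

    Attributes
    ----------
    sequences
        Uppercase strings over {A,C,G,T,N}, all of length ``L`` >= 2.
    labels
        Optional per-sequence identifiers (FASTA headers).
    motif_span
        Optional 1-based inclusive (start, end) of the aligned consensus
        core, identical for every sequence.  For start-codon-aligned
        coding sets this records the ATG anchor.
    """

    sequences: tuple[str, ...]
    labels: tuple[str, ...] | None = None
    motif_span: tuple[int, int] | None = None
    source: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise EmptyInputError("sequence set is empty")
        L = len(self.sequences[0])
        if L < 2:
            raise ValidationError(f"sequences must have length >= 2, got {L}")
        for idx, s in enumerate(self.sequences):
            if len(s) != L:
                raise FormatError(
                    f"sequence {idx + 1} has length {len(s)}, expected {L}"
                )
            if not set(s) <= _VALID:
                raise FormatError(
                    f"sequence {idx + 1} contains characters outside ACGTN"
                )
        if self.labels is not None and len(self.labels) != len(self.sequences):
            raise ValidationError("labels and sequences differ in number")
        if self.motif_span is not None:
            a, b = self.motif_span
            if not (1 <= a <= b <= L):
                raise ValidationError(f"motif_span {self.motif_span} outside 1..{L}")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        """Alignment length L; base positions are 1..L, linkages 1..L-1."""
        return len(self.sequences[0])

    @property
    def n_linkages(self) -> int:
        return self.length - 1

    def motif_columns(self) -> "SequenceSet":
        """Subset the alignment to the consensus-core columns."""
        if self.motif_span is None:
            raise ValidationError("sequence set has no motif_span")
        a, b = self.motif_span
        return SequenceSet(
            sequences=tuple(s[a - 1 : b] for s in self.sequences),
            labels=self.labels,
            motif_span=(1, b - a + 1),
            source=self.source,
        )


# ----------------------------------------------------------------------
# alignment helpers

def _center_index(length: int) -> int:
    """0-based center with the left-of-middle tie rule for even lengths.

    1-based convention: center = floor((L+1)/2).
    """
    return (length + 1) // 2 - 1


def _center_window(seq: str, span: int) -> str:
    """Window of ``span`` characters about the sequence center (same tie rule)."""
    c = _center_index(len(seq))
    start = c - _center_index(span)
    return seq[start : start + span]


# ----------------------------------------------------------------------
# readers

def read_plain(path: str | Path) -> SequenceSet:
    """Read the plain dialect: one pre-aligned sequence per line.

    Lengths must agree; a ragged line raises :class:`FormatError`
    naming the offending line.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    seqs = [_clean(ln) for ln in lines if ln]
    if not seqs:
        raise EmptyInputError(f"no sequences in {path}")
    L = len(seqs[0])
    for i, s in enumerate(seqs):
        if len(s) != L:
            raise FormatError(
                f"{path}: line {i + 1} has length {len(s)}, expected {L} "
                "(plain dialect requires pre-aligned sequences)"
            )
    return SequenceSet(sequences=tuple(seqs), source=str(path))


def _parse_fasta(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    try:
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(path, "fasta")]
    except (ValueError, AttributeError) as exc:  # malformed record
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise FormatError(f"{path}: FASTA must start with a '>' header")
    return records


def read_fasta(path: str | Path) -> SequenceSet:
    """Read standard FASTA and center-align all records.

    Records are trimmed to the shortest record's span about each
    record's own midpoint (flanks around any consensus are assumed
    equal on both sides).  Gaps are removed before alignment.
    """
    records = _parse_fasta(path)
    labels = tuple(r[0] for r in records)
    seqs = [_clean(r[1]) for r in records]
    span = min(len(s) for s in seqs)
    if span < 2:
        raise FormatError(f"{path}: shortest record has length {span} (< 2)")
    aligned = tuple(_center_window(s, span) for s in seqs)
    return SequenceSet(sequences=aligned, labels=labels, source=str(path))


_UPPER_RUN = re.compile(r"[A-Z]+")


def read_jaspar_fasta(path: str | Path) -> SequenceSet:
    """Read JASPAR-style FASTA: uppercase consensus core, lowercase flanks.

    Records are shifted so the centers of their uppercase runs coincide
    and flanks trimmed to the largest width common to all records; the
    common consensus span is recorded as ``motif_span``.  A record with
    zero or more than one maximal uppercase run violates the dialect.
    """
    records = _parse_fasta(path)
    labels = tuple(r[0] for r in records)
    cleaned, centers, runs = [], [], []
    for name, raw in records:
        seq = raw.translate(_GAPS)
        matches = _UPPER_RUN.findall(seq)
        if len(matches) != 1:
            raise DialectError(
                f"record {name!r}: expected exactly one uppercase consensus run, "
                f"found {len(matches)}"
            )
        m = _UPPER_RUN.search(seq)
        s, e = m.start(), m.end()  # 0-based, half-open
        c = s + _center_index(e - s)
        cleaned.append(_clean(seq))
        centers.append(c)
        runs.append((s, e))
    if len({e - s for s, e in runs}) > 1:
        warnings.warn(
            "uppercase motifs differ in length; trimming to the common span",
            stacklevel=2,
        )
    left = min(centers)
    right = min(len(seq) - c - 1 for seq, c in zip(cleaned, centers))
    aligned = tuple(
        seq[c - left : c + right + 1] for seq, c in zip(cleaned, centers)
    )
    motif_left = min(c - s for (s, _e), c in zip(runs, centers))
    motif_right = min(e - 1 - c for (_s, e), c in zip(runs, centers))
    motif_span = (left - motif_left + 1, left + motif_right + 1)
    return SequenceSet(
        sequences=aligned, labels=labels, motif_span=motif_span, source=str(path)
    )


_READERS = {"plain": read_plain, "fasta": read_fasta, "jaspar": read_jaspar_fasta}


def read_sequences(path: str | Path, filetype: str) -> SequenceSet:
    """Dispatch on dialect tag: ``plain``, ``fasta`` or ``jaspar``."""
    try:
        reader = _READERS[filetype]
    except KeyError:
        raise ValidationError(
            f"unknown filetype {filetype!r}; recognized values: "
            + ", ".join(sorted(_READERS))
        ) from None
    return reader(path)


# ----------------------------------------------------------------------
# writers

def write_plain(seqs: SequenceSet, path: str | Path) -> None:
    Path(path).write_text("".join(s + "\n" for s in seqs.sequences))


def _fasta_lines(seqs: SequenceSet, transform) -> str:
    labels = seqs.labels or tuple(f"seq{i + 1}" for i in range(seqs.n))
    return "".join(
        f">{name}\n{transform(s)}\n" for name, s in zip(labels, seqs.sequences)
    )


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    Path(path).write_text(_fasta_lines(seqs, lambda s: s))


def write_jaspar_fasta(seqs: SequenceSet, path: str | Path) -> None:
    """Write FASTA with the motif core uppercase and flanks lowercase."""
    if seqs.motif_span is None:
        raise ValidationError("jaspar dialect requires a motif_span")
    a, b = seqs.motif_span

    def case(s: str) -> str:
        return s[: a - 1].lower() + s[a - 1 : b] + s[b:].lower()

    Path(path).write_text(_fasta_lines(seqs, case))


def write_pwm(matrix, path: str | Path) -> None:
    """Write a position weight matrix as TSV.

    Rows are symbols, columns are 1-based positions.  Accepts a
    :class:`~flexlogo.infocontent.BasePWM`, a linkage-state matrix, or a
    plain DataFrame with symbol index.  Columns where any symbol was
    observed must sum to 1 (+/- 1e-9).
    """
    frame = matrix.to_frame() if hasattr(matrix, "to_frame") else pd.DataFrame(matrix)
    sums = frame.to_numpy().sum(axis=0)
    observed = sums > 0
    if np.any(np.abs(sums[observed] - 1.0) > 1e-9):
        bad = int(np.argmax(np.abs(sums - 1.0) * observed)) + 1
        raise ValidationError(f"PWM column {bad} does not sum to 1")
    frame = frame.copy()
    frame.columns = range(1, frame.shape[1] + 1)
    frame.to_csv(path, sep="\t", index_label="symbol", float_format="%.12g")


def read_pwm(path: str | Path) -> pd.DataFrame:
    """Read a PWM written by :func:`write_pwm`; symbol index, 1-based columns."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.columns = frame.columns.astype(int)
    return frame
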