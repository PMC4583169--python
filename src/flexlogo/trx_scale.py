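"""The TRX dinucleotide flexibility scale.

The TRX scale (twist, roll, X-displacement) is an empirical dinucleotide
metric giving the percentage of time a phosphate linkage occupies the
BII backbone conformation of B-DNA in free solution — a proxy for the
intrinsic flexibility that underlies indirect (shape) readout in
DNA-protein recognition.  Because a linkage and its reverse-complement
read identically from either strand, the 16 dimers collapse into 10
strand-symmetric classes; two of those classes share the same score, so
the linkage alphabet used for information-content calculations has
exactly 9 symbols.

Scores range from 0 (no BII occupancy, stiff) to 43 (high flexibility)
and rise with the GC content of the dimer.  The table ships as an
editable tab-delimited file (``data/trx_table.tsv``) and is validated
against those structural invariants at load time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from scipy.stats import spearmanr

from .errors import AmbiguousDimerError, ValidationError

__all__ = ["TRXScale", "reverse_complement", "load_scale", "default_scale"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Score range of the scale: percent of time in the BII conformation.
TRX_MIN = 0.0
TRX_MAX = 43.0


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string (case-insensitive, returns upper)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TRXScale:
    """Mapping from dinucleotides to strand-symmetric classes and TRX scores.

    Parameters
    ----------
    class_of
        Map from each of the 16 ACGT dimers to one of 10 class labels.
    score_of
        Map from class label to TRX score in [0, 43].
    """

    class_of: dict[str, str]
    score_of: dict[str, float]

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    @property
    def symbols(self) -> tuple[float, ...]:
        """The 9 distinct TRX scores, ascending — the linkage alphabet."""
        return tuple(sorted(set(self.score_of.values())))

    @property
    def k(self) -> int:
        """Alphabet size for linkage information content (9)."""
        return len(self.symbols)

    # ------------------------------------------------------------------
    def dinucleotide_class(self, dimer: str) -> str:
        """Canonical strand-symmetric class label of a dimer.

        ``dinucleotide_class(d) == dinucleotide_class(reverse_complement(d))``
        for every ACGT dimer.  A dimer containing any non-ACGT character
        (N, IUPAC ambiguity, gap) raises :class:`AmbiguousDimerError`;
        callers that tally frequencies mask such dimers instead.
        """
        d = dimer.upper()
        if len(d) != 2 or d not in self.class_of:
            raise AmbiguousDimerError(f"not an unambiguous ACGT dimer: {dimer!r}")
        return self.class_of[d]

    def trx_score(self, dimer: str) -> float:
        """TRX score of a dimer; NaN for ambiguous dimers (missing value)."""
        try:
            return self.score_of[self.dinucleotide_class(dimer)]
        except AmbiguousDimerError:
            return math.nan

    def state_symbol(self, dimer: str) -> float | None:
        """One of the 9 linkage-state symbols, or None for ambiguous dimers.

        The symbol is the numeric score itself, so the two classes that
        share a score map to the same symbol and the alphabet size is 9.
        """
        s = self.trx_score(dimer)
        return None if math.isnan(s) else s

    @staticmethod
    def shade(mean_trx: float) -> float:
        """Linear gray level for a mean TRX score: 0 -> 0.0 (black), 43 -> 1.0 (white)."""
        if not TRX_MIN <= mean_trx <= TRX_MAX:
            raise ValidationError(
                f"mean TRX {mean_trx!r} outside [{TRX_MIN:g}, {TRX_MAX:g}]"
            )
        return float(mean_trx) / TRX_MAX

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants of the scale; raise ValidationError."""
        dimers = {a + b for a in "ACGT" for b in "ACGT"}
        if set(self.class_of) != dimers:
            raise ValidationError("scale must cover exactly the 16 ACGT dimers")
        classes = set(self.class_of.values())
        if len(classes) != 10:
            raise ValidationError(f"expected 10 strand-symmetric classes, got {len(classes)}")
        if classes != set(self.score_of):
            raise ValidationError("class labels of class_of and score_of disagree")
        for d in dimers:
            if self.class_of[d] != self.class_of[reverse_complement(d)]:
                raise ValidationError(f"class of {d} differs from its reverse complement")
        scores = sorted(self.score_of.values())
        distinct = sorted(set(scores))
        if len(distinct) != 9:
            raise ValidationError(f"expected 9 distinct TRX scores, got {len(distinct)}")
        if min(scores) != TRX_MIN or max(scores) != TRX_MAX:
            raise ValidationError("TRX scores must span exactly [0, 43]")
        # exactly one score carried by exactly two classes
        shared = [s for s in distinct if scores.count(s) == 2]
        if len(shared) != 1 or len(scores) - len(distinct) != 1:
            raise ValidationError("exactly one score must be shared by exactly two classes")
        gc = [sum(c in "GC" for c in label) / 2 for label in self.score_of]
        rho = spearmanr(gc, [self.score_of[label] for label in self.score_of]).statistic
        if not rho > 0:
            raise ValidationError("TRX scores must correlate positively with dimer GC content")


def load_scale(path: str | Path) -> TRXScale:
    """Load a TRX table from a tab-delimited file.

    Three columns per row: class label, comma-separated member dimers,
    score.  Lines starting with ``#`` are comments.
    """
    class_of: dict[str, str] = {}
    score_of: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            label, dimers, score = line.split("\t")
        except ValueError as exc:
            raise ValidationError(f"malformed TRX table line: {raw!r}") from exc
        score_of[label] = float(score)
        for d in dimers.split(","):
            d = d.strip().upper()
            class_of[d] = label
            class_of[reverse_complement(d)] = label
    return TRXScale(class_of=class_of, score_of=score_of)


def default_scale() -> TRXScale:
    """The packaged TRX table."""
    with resources.as_file(
        resources.files("flexlogo") / "data" / "trx_table.tsv"
    ) as p:
        return load_scale(p)
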