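"""Synthetic sequence generators with the structure the analyses assume.

Two generators: transcription-factor binding sites (a conserved
consensus core plus i.i.d. flanks, mimicking center-aligned consensus
matches with short flanking regions) and start-codon-aligned coding
sequences (random 5' UTR + ATG + codons drawn from a usage table).
They exist so every analysis in the package can be exercised and
calibrated without genome downloads; they emulate positional frequency
structure only, not phylogeny or genomic context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .seq_io import SequenceSet

__all__ = [
    "IUPAC",
    "MotifSpec",
    "generate_tfbs_set",
    "sense_codons",
    "generate_coding_set",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class MotifSpec:
    """Recipe for a synthetic TFBS set.

    ``conservation`` is the probability that a motif position carries a
    consensus-consistent base (uniform over the consensus set); with
    probability 1 - conservation a base is drawn uniformly from the
    off-consensus complement.  Flanks are i.i.d. with the given GC
    fraction.  The default 7 bp flank mirrors a center-aligned
    consensus with short flanking regions; use 25 bp for genome-style
    flank analyses.
    """

    consensus: str = "CACGTG"
    conservation: float = 0.85
    flank_length: int = 7
    flank_gc: float = 0.5
    n: int = 500
    seed: int = 0
    conservation_per_position: tuple[float, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.consensus or any(c.upper() not in IUPAC for c in self.consensus):
            raise ValidationError(f"invalid IUPAC consensus {self.consensus!r}")
        cons = self.position_conservation
        if any(not 0.0 <= c <= 1.0 for c in cons):
            raise ValidationError("conservation must lie in [0, 1]")
        if not 0.0 <= self.flank_gc <= 1.0:
            raise ValidationError("flank_gc must lie in [0, 1]")
        if self.n < 1 or self.flank_length < 0:
            raise ValidationError("need n >= 1 and flank_length >= 0")

    @property
    def position_conservation(self) -> tuple[float, ...]:
        if self.conservation_per_position is not None:
            if len(self.conservation_per_position) != len(self.consensus):
                raise ValidationError("per-position conservation length mismatch")
            return tuple(self.conservation_per_position)
        return tuple([self.conservation] * len(self.consensus))


def _column_probs(symbol: str, conservation: float) -> np.ndarray:
    """Per-base sampling probabilities for one consensus position."""
    allowed = IUPAC[symbol.upper()]
    probs = np.zeros(4)
    bases = "ACGT"
    for b in allowed:
        probs[bases.index(b)] = conservation / len(allowed)
    others = [b for b in bases if b not in allowed]
    for b in others:
        probs[bases.index(b)] = (1.0 - conservation) / len(others)
    if not others:  # N column: always uniform over all four
        probs[:] = 0.25
    return probs


def generate_tfbs_set(spec: MotifSpec) -> SequenceSet:
    """Sample a center-aligned TFBS set: flank + motif + flank.

    Returns a :class:`SequenceSet` with ``motif_span`` marking the
    consensus core, writable in the jaspar dialect (uppercase core,
    lowercase flanks).
    """
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))
    m = len(spec.consensus)
    cols = [
        _column_probs(sym, c)
        for sym, c in zip(spec.consensus, spec.position_conservation)
    ]
    motif = np.stack(
        [bases[rng.choice(4, size=spec.n, p=p)] for p in cols], axis=1
    )
    gc = spec.flank_gc
    flank_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    total_flank = 2 * spec.flank_length
    flanks = bases[rng.choice(4, size=(spec.n, total_flank), p=flank_p)]
    left, right = flanks[:, : spec.flank_length], flanks[:, spec.flank_length :]
    seqs = tuple(
        "".join(l) + "".join(mo) + "".join(r)
        for l, mo, r in zip(left, motif, right)
    )
    return SequenceSet(
        sequences=seqs,
        motif_span=(spec.flank_length + 1, spec.flank_length + m),
    )


def sense_codons() -> tuple[str, ...]:
    """The 61 sense codons of the standard genetic code."""
    bases = "TCAG"
    return tuple(
        a + b + c
        for a in bases for b in bases for c in bases
        if a + b + c not in _STOPS
    )


def generate_coding_set(
    n_genes: int,
    n_codons: int,
    codon_weights=None,
    utr_length: int = 9,
    utr_composition=None,
    seed: int = 0,
) -> SequenceSet:
    """Sample start-codon-aligned synthetic genes: UTR + ATG + codons.

    ``n_codons`` counts the total codons including the forced initial
    ATG; the remaining ``n_codons - 1`` are drawn i.i.d. from
    ``codon_weights`` over the 61 sense codons (uniform by default).
    The ATG anchor is recorded as ``motif_span``.
    """
    if n_genes < 1 or n_codons < 1:
        raise ValidationError("need n_genes >= 1 and n_codons >= 1")
    codons = sense_codons()
    if codon_weights is None:
        w = np.full(len(codons), 1.0 / len(codons))
    else:
        w = np.asarray(codon_weights, dtype=float)
        if w.shape != (len(codons),) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"codon_weights must be {len(codons)} non-negative values summing to 1"
            )
    comp = (
        np.full(4, 0.25) if utr_composition is None
        else np.asarray(utr_composition, dtype=float)
    )
    if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
        raise ValidationError("utr_composition must be 4 non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    codon_arr = np.array(codons)
    seqs = []
    for _ in range(n_genes):
        utr = "".join(bases[rng.choice(4, size=utr_length, p=comp)])
        body = "".join(codon_arr[rng.choice(len(codons), size=n_codons - 1, p=w)])
        seqs.append(utr + "ATG" + body)
    anchor = utr_length + 1
    return SequenceSet(sequences=tuple(seqs), motif_span=(anchor, anchor + 2))
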