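"""Shannon information content at nucleobases and phosphate linkages.

For an aligned set of sequences the information content at position *i*
is

    IC_i = log2(k) - H_i,      H_i = - sum_s p_{s,i} log2(p_{s,i})

where ``p_{s,i}`` is the relative frequency of symbol *s* at *i* and
*k* is the alphabet size: 4 for nucleobases (cap log2(4) = 2.0 bits)
and 9 for the TRX linkage-state alphabet (cap log2(9) ~ 3.17 bits).
For display and base-vs-linkage comparison, linkage IC is rescaled
linearly onto the 2.0-bit axis of a conventional four-letter logo.

Ambiguous bases (N) are masked: an N is excluded from the frequency
count of its own column and of both adjacent linkages.  A column where
nothing was observed is flagged and rendered with zero height.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .seq_io import SequenceSet
from .trx_scale import TRXScale

__all__ = [
    "BASES",
    "BasePWM",
    "LinkageStateMatrix",
    "LogoProfile",
    "base_pwm",
    "linkage_state_matrix",
    "entropy",
    "information_content",
    "normalize_linkage_ic",
    "mean_trx_profile",
    "logo_profile",
]

BASES = ("A", "C", "G", "T")

LINKAGE_CAP = float(np.log2(9))  # raw cap of the 9-state alphabet
BASE_CAP = 2.0


@dataclass(frozen=True)
class BasePWM:
    """Positional relative frequencies over the 4-base alphabet.

    ``p[s, i]`` is the frequency of base ``alphabet[s]`` at 0-based
    column ``i`` among non-N observations; ``n_eff[i]`` counts those
    observations.
    """

    p: np.ndarray  # (4, L)
    n_eff: np.ndarray  # (L,)
    alphabet: tuple[str, ...] = BASES
    k: int = 4

    def __post_init__(self) -> None:
        _check_columns(self.p, self.n_eff)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=list(self.alphabet))


@dataclass(frozen=True)
class LinkageStateMatrix:
    """Positional relative frequencies over the 9 TRX linkage states.

    Rows are the distinct TRX scores (ascending); column *j* describes
    the linkage between bases *j+1* and *j+2* (1-based linkage j+1).
    """

    p: np.ndarray  # (9, L-1)
    n_eff: np.ndarray  # (L-1,)
    alphabet: tuple[float, ...]
    k: int = 9

    def __post_init__(self) -> None:
        if len(self.alphabet) != 9 or self.p.shape[0] != 9:
            raise ValidationError("linkage alphabet must have exactly 9 symbols")
        _check_columns(self.p, self.n_eff)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=[f"{s:g}" for s in self.alphabet])


def _check_columns(p: np.ndarray, n_eff: np.ndarray) -> None:
    if p.ndim != 2 or n_eff.shape != (p.shape[1],):
        raise ValidationError("frequency matrix and n_eff shapes disagree")
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("frequencies must lie in [0, 1]")
    observed = n_eff > 0
    sums = p.sum(axis=0)
    if np.any(np.abs(sums[observed] - 1.0) > 1e-9):
        raise ValidationError("observed columns must sum to 1")


# ----------------------------------------------------------------------

def base_pwm(seqs: SequenceSet) -> BasePWM:
    """Tally per-column base frequencies, masking N."""
    arr = np.frombuffer(
        "".join(seqs.sequences).encode(), dtype="S1"
    ).reshape(seqs.n, seqs.length)
    counts = np.stack([(arr == b.encode()).sum(axis=0) for b in BASES]).astype(float)
    n_eff = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_eff > 0, counts / np.where(n_eff > 0, n_eff, 1), 0.0)
    return BasePWM(p=p, n_eff=n_eff)


def linkage_state_matrix(seqs: SequenceSet, scale: TRXScale) -> LinkageStateMatrix:
    """Tally per-linkage TRX-state frequencies.

    At linkage *j* each sequence contributes the state symbol of its
    dimer (base j, base j+1); dimers containing N are excluded.
    """
    symbols = scale.symbols
    index = {s: r for r, s in enumerate(symbols)}
    L = seqs.length
    arr = np.frombuffer("".join(seqs.sequences).encode(), dtype=np.uint8)
    arr = arr.reshape(seqs.n, L)
    base_code = np.full(256, 4, dtype=np.int64)  # 4 = ambiguous
    for c, b in enumerate(b"ACGT"):
        base_code[b] = c
    coded = base_code[arr]
    dimer = coded[:, :-1] * 5 + coded[:, 1:]  # 25 codes; any code >= 20 or %5==4 has N
    row_of = np.full(25, -1, dtype=np.int64)
    for a in range(4):
        for b in range(4):
            row_of[a * 5 + b] = index[scale.state_symbol(BASES[a] + BASES[b])]
    rows = row_of[dimer]  # (n, L-1), -1 where the dimer contains N
    counts = np.zeros((9, L - 1))
    for r in range(9):
        counts[r] = (rows == r).sum(axis=0)
    n_eff = counts.sum(axis=0)
    p = np.where(n_eff > 0, counts / np.where(n_eff > 0, n_eff, 1), 0.0)
    return LinkageStateMatrix(p=p, n_eff=n_eff, alphabet=symbols)


def entropy(p, k: int | None = None) -> float | np.ndarray:
    """Shannon entropy in bits of one frequency column (0*log 0 := 0).

    Accepts a 1-D column or a (k, L) matrix, returning a scalar or a
    per-column vector.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValidationError("negative frequency")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    h = -terms.sum(axis=0)
    return float(h) if np.ndim(h) == 0 else h


def information_content(h, k: int):
    """IC = log2(k) - H, elementwise; H must not exceed log2(k)."""
    h = np.asarray(h, dtype=float)
    cap = np.log2(k)
    if np.any(h > cap + 1e-9) or np.any(h < -1e-9):
        raise ValidationError(f"entropy outside [0, log2({k})]")
    ic = np.clip(cap - h, 0.0, cap)
    return float(ic) if np.ndim(ic) == 0 else ic


def normalize_linkage_ic(ic_raw):
    """Rescale raw 9-state IC (cap log2 9) onto the 2.0-bit display axis."""
    ic_raw = np.asarray(ic_raw, dtype=float)
    if np.any(ic_raw < -1e-9) or np.any(ic_raw > LINKAGE_CAP + 1e-9):
        raise ValidationError("raw linkage IC outside [0, log2(9)]")
    out = np.clip(ic_raw, 0.0, LINKAGE_CAP) * (BASE_CAP / LINKAGE_CAP)
    return float(out) if np.ndim(out) == 0 else out


def mean_trx_profile(seqs: SequenceSet, scale: TRXScale) -> np.ndarray:
    """Average TRX score of observed dimers at each linkage; NaN if unobserved."""
    m = linkage_state_matrix(seqs, scale)
    means = np.asarray(m.alphabet) @ m.p
    return np.where(m.n_eff > 0, means, np.nan)


def _small_sample_correction(k: int, n) -> np.ndarray:
    """Classic logo small-sample bias term e(n) = (k-1) / (2 ln2 * n)."""
    n = np.asarray(n, dtype=float)
    return np.where(n > 0, (k - 1) / (2 * np.log(2) * np.where(n > 0, n, 1)), 0.0)


@dataclass(frozen=True)
class LogoProfile:
    """Everything a flexibility-annotated sequence logo needs.

    Base arrays have length L (positions 1..L); linkage arrays length
    L-1 (linkage j between bases j and j+1).  Unobserved columns carry
    IC 0 and are flagged in ``base_observed`` / ``link_observed``.
    """

    ic_base: np.ndarray
    h_base: np.ndarray
    base_freqs: np.ndarray  # (4, L)
    ic_link_raw: np.ndarray
    ic_link_norm: np.ndarray
    mean_trx: np.ndarray
    base_observed: np.ndarray
    link_observed: np.ndarray
    L: int
    n: int
    normalized: bool = True
    alphabet: tuple[str, ...] = BASES
    link_alphabet: tuple[float, ...] = field(default=())

    @property
    def ic_link(self) -> np.ndarray:
        """The linkage IC on the scale selected at construction."""
        return self.ic_link_norm if self.normalized else self.ic_link_raw

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: one row per base position, linkage j on row j."""
        L = self.L
        pad = [np.nan]
        df = pd.DataFrame({"position": np.arange(1, L + 1), "ic_base": self.ic_base})
        for r, b in enumerate(self.alphabet):
            df[f"p_{b}"] = self.base_freqs[r]
        df["ic_link_raw"] = np.concatenate([self.ic_link_raw, pad])
        df["ic_link_norm"] = np.concatenate([self.ic_link_norm, pad])
        df["mean_trx"] = np.concatenate([self.mean_trx, pad])
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def logo_profile(
    seqs: SequenceSet,
    scale: TRXScale,
    normalize: bool = True,
    small_sample_correction: bool = False,
) -> LogoProfile:
    """Compute the full per-position information/flexibility profile.

    Parameters
    ----------
    normalize
        If True (default) ``ic_link`` is the 2.0-bit display scale;
        raw 9-state bits remain available as ``ic_link_raw``.
    small_sample_correction
        Subtract the classic e(n) bias term from IC (off by default;
        the plain equations above are the default contract).
    """
    pwm = base_pwm(seqs)
    lsm = linkage_state_matrix(seqs, scale)
    h_base = entropy(pwm.p)
    ic_base = information_content(h_base, 4)
    ic_link_raw = information_content(entropy(lsm.p), 9)
    if small_sample_correction:
        ic_base = np.clip(ic_base - _small_sample_correction(4, pwm.n_eff), 0.0, None)
        ic_link_raw = np.clip(
            ic_link_raw - _small_sample_correction(9, lsm.n_eff), 0.0, None
        )
    base_observed = pwm.n_eff > 0
    link_observed = lsm.n_eff > 0
    ic_base = np.where(base_observed, ic_base, 0.0)
    ic_link_raw = np.where(link_observed, ic_link_raw, 0.0)
    means = np.asarray(lsm.alphabet) @ lsm.p
    return LogoProfile(
        ic_base=ic_base,
        h_base=np.where(base_observed, h_base, np.nan),
        base_freqs=pwm.p,
        ic_link_raw=ic_link_raw,
        ic_link_norm=normalize_linkage_ic(ic_link_raw),
        mean_trx=np.where(link_observed, means, np.nan),
        base_observed=base_observed,
        link_observed=link_observed,
        L=seqs.length,
        n=seqs.n,
        normalized=normalize,
        link_alphabet=lsm.alphabet,
    )
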