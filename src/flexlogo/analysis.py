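"""Statistical comparisons of base-level and linkage-level information.

Four procedures:

* Welch t-tests comparing mean base IC with mean linkage IC over a
  region (binding site or flank), with family-wise Bonferroni control
  across many motifs.
* A codon-phase scan of start-codon-aligned coding sequences: linkage
  IC bucketed by position relative to the reading frame into the four
  phases x-1 (junction preceding a codon), 1-2, 2-3 (internal) and 3-z
  (junction following), where x and z denote bases of adjoining codons.
* A bootstrap one-way ANOVA over random gene subsets testing equality
  of the four phase means.
* A codon-context scan: pooled codons flanked by random DNA of equal
  base composition, which removes gene-specific sequence information
  and leaves only the structure of the genetic code itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .infocontent import logo_profile
from .seq_io import SequenceSet
from .trx_scale import TRXScale

__all__ = [
    "ICComparisonResult",
    "CodonPhaseSummary",
    "BootstrapAnovaResult",
    "CodonContextResult",
    "compare_base_vs_linkage_ic",
    "bonferroni",
    "codon_phase_ic",
    "bootstrap_anova",
    "random_dna",
    "codon_context_scan",
]

PHASES = ("x-1", "1-2", "2-3", "3-z")


@dataclass(frozen=True)
class ICComparisonResult:
    """Base-vs-linkage IC comparison over one region."""

    region: tuple[int, int]
    mean_base_ic: float
    mean_link_ic: float
    t: float
    p: float
    paired: bool = False
    adjusted_alpha: float | None = None
    significant: bool | None = None

    def with_correction(self, adjusted_alpha: float) -> "ICComparisonResult":
        from dataclasses import replace

        return replace(
            self, adjusted_alpha=adjusted_alpha, significant=bool(self.p < adjusted_alpha)
        )


def compare_base_vs_linkage_ic(
    profile,
    region: tuple[int, int] | None = None,
    use_normalized: bool = True,
    paired: bool = False,
) -> ICComparisonResult:
    """Welch (or paired) t-test of base IC against linkage IC in a region.

    ``region`` is a 1-based inclusive base-position range; the linkages
    compared are those wholly inside it (positions a..b-1).  Welch is
    the default because the region holds b-a+1 base positions but only
    b-a linkages; ``paired=True`` instead pairs base i with linkage i.
    """
    a, b = region if region is not None else (1, profile.L)
    if not (1 <= a < b <= profile.L):
        raise InsufficientDataError(
            f"region {a}..{b} needs at least 2 base positions within 1..{profile.L}"
        )
    base = np.asarray(profile.ic_base[a - 1 : b], dtype=float)
    link_arr = profile.ic_link_norm if use_normalized else profile.ic_link_raw
    link = np.asarray(link_arr[a - 1 : b - 1], dtype=float)
    if link.size < 2:
        raise InsufficientDataError("region contains fewer than 2 linkages")
    if paired:
        res = stats.ttest_rel(base[: link.size], link)
    else:
        res = stats.ttest_ind(base, link, equal_var=False)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero variance in both samples: identical constants
        t, p = 0.0, 1.0
    return ICComparisonResult(
        region=(a, b),
        mean_base_ic=float(base.mean()),
        mean_link_ic=float(link.mean()),
        t=t,
        p=p,
        paired=paired,
    )


def bonferroni(p_values, family_alpha: float = 0.05):
    """Family-wise Bonferroni decisions: reject iff p < alpha / m.

    Returns (decisions, threshold); order-invariant.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size < 1:
        raise ValidationError("need at least one p value")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p values must lie in [0, 1]")
    threshold = family_alpha / p.size
    return (p < threshold).tolist(), threshold


# ----------------------------------------------------------------------
# codon-phase analysis

@dataclass(frozen=True)
class CodonPhaseSummary:
    """Mean linkage IC at the four codon-bridging phases plus ANOVA."""

    phase_means: dict[str, float]
    phase_n: dict[str, int]
    phase_values: dict[str, np.ndarray]
    f_statistic: float | None
    p_value: float | None
    n_codons: int

    @property
    def internal_minus_external(self) -> float:
        """Mean of internal phases (1-2, 2-3) minus external (x-1, 3-z)."""
        internal = (self.phase_means["1-2"] + self.phase_means["2-3"]) / 2
        external = (self.phase_means["x-1"] + self.phase_means["3-z"]) / 2
        return internal - external


def _phase_positions(anchor: int, L: int, n_codons: int | None):
    """1-based linkage positions per phase for a start-aligned window.

    The linkage after codon c is simultaneously 3-z of c and x-1 of
    c+1; to keep the four groups disjoint those junctions alternate
    (odd c -> 3-z, even c -> x-1) and the UTR|ATG junction goes to x-1.
    """
    C = (L - anchor + 1) // 3
    if n_codons is not None:
        C = min(C, n_codons)
    if C < 2:
        raise InsufficientDataError("need at least 2 full codons downstream of anchor")
    pos = {ph: [] for ph in PHASES}
    if anchor >= 2:
        pos["x-1"].append(anchor - 1)
    for c in range(1, C + 1):
        first = anchor + 3 * (c - 1)
        pos["1-2"].append(first)
        pos["2-3"].append(first + 1)
        if c < C:  # junction between codon c and c+1
            pos["3-z" if c % 2 == 1 else "x-1"].append(first + 2)
    return pos, C


def codon_phase_ic(
    seqs: SequenceSet,
    scale: TRXScale,
    anchor: int | None = None,
    n_codons: int | None = None,
    use_normalized: bool = True,
) -> CodonPhaseSummary:
    """Bucket downstream linkage IC by codon phase and test equality.

    ``anchor`` is the 1-based position of the A of the start codon
    (defaults to ``motif_span[0]``).  A warning is issued if more than
    half the sequences lack ATG at the anchor.
    """
    if anchor is None:
        if seqs.motif_span is None:
            raise ValidationError("no anchor given and no motif_span recorded")
        anchor = seqs.motif_span[0]
    if not 1 <= anchor <= seqs.length - 2:
        raise ValidationError(f"anchor {anchor} outside 1..{seqs.length - 2}")
    atg = sum(s[anchor - 1 : anchor + 2] == "ATG" for s in seqs.sequences)
    if atg * 2 < seqs.n:
        warnings.warn(
            f"only {atg}/{seqs.n} sequences carry ATG at anchor {anchor}; "
            "start codons may be misaligned",
            stacklevel=2,
        )
    profile = logo_profile(seqs, scale)
    ic = profile.ic_link_norm if use_normalized else profile.ic_link_raw
    pos, C = _phase_positions(anchor, seqs.length, n_codons)
    values = {ph: np.asarray([ic[j - 1] for j in pos[ph]]) for ph in PHASES}
    groups = [values[ph] for ph in PHASES if values[ph].size >= 2]
    if len(groups) == 4:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_res = stats.f_oneway(*groups)
        f_stat, p_val = float(f_res.statistic), float(f_res.pvalue)
        if np.isnan(f_stat):  # all groups constant and equal
            f_stat, p_val = 0.0, 1.0
    else:
        f_stat = p_val = None
    return CodonPhaseSummary(
        phase_means={ph: float(values[ph].mean()) for ph in PHASES},
        phase_n={ph: int(values[ph].size) for ph in PHASES},
        phase_values=values,
        f_statistic=f_stat,
        p_value=p_val,
        n_codons=C,
    )


@dataclass(frozen=True)
class BootstrapAnovaResult:
    """One-way ANOVA over bootstrap-replicate phase means."""

    f_statistic: float
    p_value: float
    phase_means: dict[str, float]
    n_sets: int
    set_size: int
    seed: int


def bootstrap_anova(
    genes: SequenceSet,
    scale: TRXScale,
    n_sets: int = 100,
    set_size: int = 10,
    seed: int = 0,
    anchor: int | None = None,
    n_codons: int | None = None,
    use_normalized: bool = True,
) -> BootstrapAnovaResult:
    """Bootstrap the codon-phase means and ANOVA them across phases.

    Draws ``n_sets`` random subsets of ``set_size`` genes (with
    replacement), computes the four per-phase mean linkage ICs for each
    subset, then runs a one-way ANOVA across the four phase groups of
    ``n_sets`` replicate means each.
    """
    if genes.n < set_size:
        raise InsufficientDataError(
            f"need at least set_size={set_size} genes, have {genes.n}"
        )
    rng = np.random.default_rng(seed)
    replicate_means = {ph: [] for ph in PHASES}
    for _ in range(n_sets):
        idx = rng.integers(0, genes.n, size=set_size)
        subset = SequenceSet(
            sequences=tuple(genes.sequences[i] for i in idx),
            motif_span=genes.motif_span,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = codon_phase_ic(
                subset, scale, anchor=anchor, n_codons=n_codons,
                use_normalized=use_normalized,
            )
        for ph in PHASES:
            replicate_means[ph].append(summary.phase_means[ph])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_res = stats.f_oneway(*(replicate_means[ph] for ph in PHASES))
    f_stat, p_val = float(f_res.statistic), float(f_res.pvalue)
    if np.isnan(f_stat):  # all replicate means constant and equal
        f_stat, p_val = 0.0, 1.0
    return BootstrapAnovaResult(
        f_statistic=f_stat,
        p_value=p_val,
        phase_means={ph: float(np.mean(replicate_means[ph])) for ph in PHASES},
        n_sets=n_sets,
        set_size=set_size,
        seed=seed,
    )


# ----------------------------------------------------------------------
# random DNA and the codon-context scan

def random_dna(length: int, base_composition=None, seed=None) -> str:
    """I.i.d. random DNA with the given (A, C, G, T) composition.

    ``seed`` may be an int or a ``numpy.random.Generator``; the same
    seed always reproduces the same sequence.
    """
    comp = (
        np.full(4, 0.25) if base_composition is None
        else np.asarray(base_composition, dtype=float)
    )
    if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
        raise ValidationError("base composition must be 4 non-negative values summing to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=comp)])


@dataclass(frozen=True)
class CodonContextResult:
    """Linkage IC of pooled codons embedded in composition-matched random DNA."""

    ic_by_phase: dict[str, float]
    flank_ic_mean: float
    profile: object
    anchor: int
    internal_ic_mean: float
    external_ic_mean: float


def codon_context_scan(
    codons,
    flank_codons: int = 2,
    base_composition=None,
    seed: int = 0,
    scale: TRXScale | None = None,
    use_normalized: bool = True,
) -> CodonContextResult:
    """Pool codons, flank each with random triplets, and profile linkage IC.

    Flanks are drawn i.i.d. with the codon pool's own base composition
    (or a user-supplied one, with a warning if it deviates from the
    pool by more than 0.05), so any IC above the flank background
    reflects the organization of the genetic code, not base content.
    """
    codons = [c.upper() for c in codons]
    if not codons:
        raise ValidationError("codon list is empty")
    if any(len(c) != 3 or set(c) - set("ACGT") for c in codons):
        raise ValidationError("codons must be 3-letter ACGT strings")
    if scale is None:
        from .trx_scale import default_scale

        scale = default_scale()
    pooled = "".join(codons)
    pool_comp = np.array([pooled.count(b) for b in "ACGT"], dtype=float)
    pool_comp /= pool_comp.sum()
    if base_composition is None:
        comp = pool_comp
    else:
        comp = np.asarray(base_composition, dtype=float)
        if np.max(np.abs(comp - pool_comp)) > 0.05:
            warnings.warn(
                "flank base composition deviates from the codon pool by more "
                "than 0.05; the flank background is no longer composition-matched",
                stacklevel=2,
            )
    rng = np.random.default_rng(seed)
    f = 3 * flank_codons
    seqs = tuple(
        random_dna(f, comp, rng) + c + random_dna(f, comp, rng) for c in codons
    )
    anchor = f + 1
    sset = SequenceSet(sequences=seqs, motif_span=(anchor, anchor + 2))
    profile = logo_profile(sset, scale)
    ic = profile.ic_link_norm if use_normalized else profile.ic_link_raw
    # 1-based linkages: x-1 at anchor-1, internal at anchor and anchor+1,
    # 3-z at anchor+2; deeper flank linkages are background.
    by_phase = {
        "x-1": float(ic[anchor - 2]),
        "1-2": float(ic[anchor - 1]),
        "2-3": float(ic[anchor]),
        "3-z": float(ic[anchor + 1]),
    }
    flank_idx = [j for j in range(len(ic)) if j < anchor - 2 or j > anchor + 1]
    return CodonContextResult(
        ic_by_phase=by_phase,
        flank_ic_mean=float(np.mean([ic[j] for j in flank_idx])),
        profile=profile,
        anchor=anchor,
        internal_ic_mean=(by_phase["1-2"] + by_phase["2-3"]) / 2,
        external_ic_mean=(by_phase["x-1"] + by_phase["3-z"]) / 2,
    )
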