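"""Base-vs-linkage comparisons, codon-phase scan, bootstrap ANOVA."""

import numpy as np
import pytest
from scipy import stats

from flexlogo import analysis
from flexlogo.errors import InsufficientDataError, ValidationError
from flexlogo.infocontent import logo_profile
from flexlogo.seq_io import SequenceSet
from flexlogo.synth import generate_coding_set


def _profile_stub(ic_base, ic_link):
    """Minimal profile-like object for comparison tests."""

    class P:
        pass

    p = P()
    p.ic_base = np.asarray(ic_base, dtype=float)
    p.ic_link_norm = np.asarray(ic_link, dtype=float)
    p.ic_link_raw = p.ic_link_norm * (np.log2(9) / 2.0)
    p.L = len(p.ic_base)
    return p


class TestCompareIC:
    def test_identical_values_give_t0_p1(self):
        prof = _profile_stub([1.0] * 10, [1.0] * 9)
        res = analysis.compare_base_vs_linkage_ic(prof)
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_constant_offset_detected(self):
        rng = np.random.default_rng(0)
        base = rng.normal(1.0, 0.05, size=26)
        link = base[:25] + 0.5 + rng.normal(0, 0.05, size=25)
        res = analysis.compare_base_vs_linkage_ic(
            _profile_stub(base, link), region=(1, 26)
        )
        assert res.p < 0.05
        assert res.mean_link_ic > res.mean_base_ic

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0.8, 0.2, size=12)
        link = rng.normal(1.0, 0.2, size=11)
        res = analysis.compare_base_vs_linkage_ic(_profile_stub(base, link))
        # permutation distribution of the Welch statistic
        pooled = np.concatenate([base, link])
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            t = stats.ttest_ind(perm[:12], perm[12:], equal_var=False).statistic
            count += abs(t) >= abs(res.t)
        assert res.p == pytest.approx(count / n_perm, abs=0.03)

    def test_single_position_region_rejected(self):
        prof = _profile_stub([1.0] * 10, [1.0] * 9)
        with pytest.raises(InsufficientDataError):
            analysis.compare_base_vs_linkage_ic(prof, region=(3, 3))

    def test_paired_mode(self):
        prof = _profile_stub([1.0, 1.2, 1.4, 1.1], [1.3, 1.5, 1.7])
        res = analysis.compare_base_vs_linkage_ic(prof, paired=True)
        assert res.paired
        assert res.p < 0.05  # constant +0.3 shift, zero within-pair variance


class TestBonferroni:
    def test_threshold_for_416_tests(self):
        decisions, threshold = analysis.bonferroni([0.5] * 416, 0.05)
        assert threshold == pytest.approx(0.05 / 416)
        assert threshold == pytest.approx(1.202e-4, rel=1e-3)
        assert not any(decisions)

    def test_single_test_uses_family_alpha(self):
        decisions, threshold = analysis.bonferroni([0.03], 0.05)
        assert threshold == 0.05
        assert decisions == [True]

    def test_order_invariant(self):
        ps = [0.001, 0.2, 0.00001, 0.9]
        d1, _ = analysis.bonferroni(ps, 0.05)
        d2, _ = analysis.bonferroni(ps[::-1], 0.05)
        assert d1 == d2[::-1]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            analysis.bonferroni([0.5, 1.5])


class TestCodonPhase:
    def test_internal_phases_exceed_external_in_coding_dna(self, scale):
        genes = generate_coding_set(n_genes=300, n_codons=40, seed=11)
        summary = analysis.codon_phase_ic(genes, scale)
        internal = min(summary.phase_means["1-2"], summary.phase_means["2-3"])
        external = max(summary.phase_means["x-1"], summary.phase_means["3-z"])
        assert internal > external
        assert summary.internal_minus_external > 0

    def test_four_phases_with_expected_counts(self, scale):
        genes = generate_coding_set(n_genes=20, n_codons=10, utr_length=5, seed=0)
        summary = analysis.codon_phase_ic(genes, scale)
        assert set(summary.phase_means) == set(analysis.PHASES)
        assert summary.phase_n["1-2"] == summary.phase_n["2-3"] == 10
        # 9 codon junctions split between the external phases + UTR junction
        assert summary.phase_n["x-1"] + summary.phase_n["3-z"] == 10

    def test_uniform_bases_show_no_phase_effect(self, scale):
        rng = np.random.default_rng(5)
        seqs = tuple(
            "".join(np.array(list("ACGT"))[rng.integers(0, 4, 120)])
            for _ in range(4000)
        )
        genes = SequenceSet(sequences=seqs, motif_span=(10, 12))
        with pytest.warns(UserWarning, match="misaligned"):
            summary = analysis.codon_phase_ic(genes, scale)
        spread = max(summary.phase_means.values()) - min(summary.phase_means.values())
        assert spread < 0.02
        assert summary.p_value > 0.001

    def test_single_gene_means_without_anova(self, scale):
        genes = generate_coding_set(n_genes=1, n_codons=5, seed=0)
        summary = analysis.codon_phase_ic(genes, scale)
        assert summary.f_statistic == 0.0 and summary.p_value == 1.0

    def test_anchor_required(self, scale):
        s = SequenceSet(sequences=("ACGTACGTT",))
        with pytest.raises(ValidationError):
            analysis.codon_phase_ic(s, scale)


class TestBootstrapAnova:
    def test_deterministic_under_seed(self, scale):
        genes = generate_coding_set(n_genes=40, n_codons=20, seed=3)
        a = analysis.bootstrap_anova(genes, scale, n_sets=20, seed=9)
        b = analysis.bootstrap_anova(genes, scale, n_sets=20, seed=9)
        assert (a.f_statistic, a.p_value) == (b.f_statistic, b.p_value)

    def test_phase_effect_detected(self, scale):
        genes = generate_coding_set(n_genes=150, n_codons=50, seed=21)
        res = analysis.bootstrap_anova(genes, scale, n_sets=100, set_size=10, seed=4)
        assert res.p_value < 0.05

    def test_constant_genes_give_f0(self, scale):
        genes = SequenceSet(sequences=("ATGCATCATCAT",) * 12, motif_span=(1, 3))
        res = analysis.bootstrap_anova(genes, scale, n_sets=10, seed=0)
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_too_few_genes(self, scale):
        genes = generate_coding_set(n_genes=5, n_codons=10, seed=0)
        with pytest.raises(InsufficientDataError):
            analysis.bootstrap_anova(genes, scale, set_size=10)


class TestRandomDNA:
    def test_degenerate_composition(self):
        assert analysis.random_dna(5, (1, 0, 0, 0), seed=0) == "AAAAA"

    def test_composition_recovered(self):
        seq = analysis.random_dna(100_000, (0.25,) * 4, seed=1)
        for b in "ACGT":
            assert seq.count(b) / len(seq) == pytest.approx(0.25, abs=0.005)

    def test_seed_reproducible(self):
        assert analysis.random_dna(50, seed=7) == analysis.random_dna(50, seed=7)

    def test_invalid_composition(self):
        with pytest.raises(ValidationError):
            analysis.random_dna(10, (0.5, 0.5, 0.5, -0.5))


class TestCodonContextScan:
    def test_single_codon_type_maximal_inside_flat_outside(self, scale):
        res = analysis.codon_context_scan(["CAT"] * 400, seed=2, scale=scale)
        assert res.internal_ic_mean > 1.9  # near the 2.0-bit cap
        # flanks lack G entirely (composition matched to CAT), which
        # restricts the 9-state alphabet and leaves a composition floor
        # well below the internal signal
        assert res.flank_ic_mean < res.internal_ic_mean - 1.5
        assert res.external_ic_mean < res.internal_ic_mean

    def test_uniform_codons_carry_no_information(self, scale):
        rng = np.random.default_rng(3)
        all64 = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
        codons = [all64[i] for i in rng.integers(0, 64, size=20_000)]
        res = analysis.codon_context_scan(codons, seed=4, scale=scale)
        assert abs(res.internal_ic_mean - res.flank_ic_mean) < 0.01

    def test_genetic_code_structure_exceeds_random_background(self, scale):
        # codons weighted by a uniform amino-acid distribution
        from flexlogo.synth import sense_codons

        rng = np.random.default_rng(6)
        table = {}
        for c in sense_codons():
            table.setdefault(_translate(c), []).append(c)
        aas = list(table)
        codons = [
            table[aas[i]][rng.integers(0, len(table[aas[i]]))]
            for i in rng.integers(0, len(aas), size=50_000)
        ]
        res = analysis.codon_context_scan(codons, seed=7, scale=scale)
        assert res.internal_ic_mean > res.flank_ic_mean

    def test_composition_mismatch_warns(self, scale):
        with pytest.warns(UserWarning, match="composition"):
            analysis.codon_context_scan(
                ["CAT"] * 50, base_composition=(0.7, 0.1, 0.1, 0.1),
                seed=0, scale=scale,
            )


_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "AGT": "S", "AGC": "S", "CCT": "P", "CCC": "P",
    "CCA": "P", "CCG": "P", "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}


def _translate(codon: str) -> str:
    return _CODE[codon]
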