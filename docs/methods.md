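# Methods

## Model

For a set of *n* center-aligned sequences of length *L*, the Shannon
information content at position *i* over an alphabet of *k* symbols is

    IC_i = log2(k) − H_i,      H_i = − Σ_s p_{s,i} log2(p_{s,i}),

with `p_{s,i}` the relative frequency of symbol *s* at *i* and
`0·log 0 := 0`. The logarithm is base 2 throughout, so IC is in bits
and the caps come out as printed on the plots: `log2(4) = 2.0` bits for
bases, `log2(9) ≈ 3.17` bits for linkages.

Two alphabets are applied to the same alignment:

* **Bases** (k = 4): the column of nucleotides at position *i*,
  positions 1..L.
* **Linkage states** (k = 9): at linkage *j* (between bases *j* and
  *j+1*, linkages 1..L−1) each sequence contributes the TRX score of
  its dinucleotide. The TRX scale assigns each of the 10
  strand-symmetric dinucleotide classes the percentage of time its
  phosphate linkage spends in the BII backbone conformation, 0–43,
  rising with GC content. The state symbol is the numeric score
  itself, so the two classes that share a score merge into one symbol
  and k = 9.

For display, and by default for base-vs-linkage comparisons, linkage
IC is rescaled linearly onto the 2.0-bit axis
(`ic_norm = ic_raw · 2/log2(9)`); raw 9-state bits are always
available (`use_normalized=False`, `--raw`). The mean TRX score at
each linkage is mapped linearly to a gray level (0 → black, 43 →
white) for the bar fill.

## TRX score table

The per-class scores ship as an editable three-column TSV
(`src/flexlogo/data/trx_table.tsv`), validated at load against the
scale's structural invariants: exactly 10 classes covering all 16
dimers with reverse-complement symmetry, exactly 9 distinct scores,
minimum 0, maximum 43, exactly one score shared by exactly two
classes, and a positive Spearman correlation between score and dimer
GC content. The shipped values place the shared minimum at ApT and
ApA/TpT (the stiff, minor-groove-narrowing steps), the YpR kinking
steps high (CpA/TpG 25, TpA 13, CpG 43), and GpC-rich steps near the
top. Analyses in this package depend on the invariants, not on the
individual values; users with a preferred transcription of the
experimental scale can drop in their own table (`--trx-table`).

## Input dialects and alignment conventions

* `plain`: one sequence per line, already aligned; ragged input is an
  error.
* `fasta`: records center-aligned by trimming every record to the
  shortest record's span about its own midpoint (flanks assumed equal
  on both sides).
* `jaspar`: uppercase consensus core, lowercase flanks; records are
  aligned on the centers of their uppercase runs, flanks trimmed to
  the largest common width, and the common core recorded as
  `motif_span`. Cores of unequal length trigger a warning and trim to
  the common span. Trimming never fabricates sequence, which is why
  unequal flanks are cut rather than padded.

Conventions, chosen once and applied everywhere: positions are
1-based; linkage *j* sits between bases *j* and *j+1*; the center of
an even-length span is taken left of middle (`floor((L+1)/2)`). Gap
characters are stripped before alignment; any other non-ACGT character
becomes N and is excluded from the frequency count of its column and
of both adjacent linkages. A column with no observations is flagged
and rendered at zero height.

## Statistics

**Base vs linkage IC.** Welch's two-sample t-test on the per-position
base IC values against the per-linkage IC values of a region (the
region's L positions vs its L−1 linkages make a paired design
unnatural, though pairing base *i* with linkage *i* is available).
Family-wise control across many motifs uses Bonferroni:
reject at `p < α/m`. Tests are two-sided with family α = 0.05 by
default.

**Codon-phase scan.** For start-aligned coding sequences (anchor = the
A of ATG, recorded by the generator as `motif_span`), per-linkage IC
values downstream of the anchor are bucketed by reading-frame phase:
1-2 and 2-3 are the linkages internal to a codon; the junction linkage
following codon *c* is simultaneously phase 3-z of *c* and phase x-1
of *c+1* (x, z denote bases of adjoining codons). To keep the four
ANOVA groups position-disjoint, junctions are assigned alternately
(after odd codons → 3-z, after even codons → x-1) and the UTR|ATG
junction goes to x-1; with ≥2 codons all four groups are non-empty.
A one-way ANOVA across the four groups tests phase equality. In the
codon-context scan (each codon flanked by random triplets drawn with
the codon pool's own base composition) the four phases are physically
distinct linkages and need no convention; composition matching removes
base-content information so that any internal-vs-flank excess reflects
the organization of the genetic code alone.

**Bootstrap ANOVA.** `n_sets` subsets of `set_size` genes are drawn
with replacement (seeded, the seed is part of the result), the four
phase means computed per subset, and a one-way ANOVA run across the
four groups of `n_sets` replicate means. Calibration caveat: the
replicate means are independent only when the gene pool is much larger
than a subset. With small pools (≲ a few hundred genes) the realized
pool-level positional noise is shared by every subset and inflates F;
in our null simulations the rejection rate at α = 0.05 is ≈ 0.05 with
a 1000-gene pool but ≈ 0.13 with a 200-gene pool and ≈ 0.45 with 30
genes. The null-calibration study therefore uses a genome-scale pool
(1000 uniform-base genes of 50 codons, 200 replicates), matching the
method's intended whole-genome setting; applying the bootstrap ANOVA
to small collections is not recommended.

## Synthetic data

`generate_tfbs_set` emulates center-aligned consensus matches: motif
positions carry a consensus-consistent base (uniform over the IUPAC
set) with probability `conservation`, otherwise a uniform
off-consensus base; flanks are i.i.d. with a chosen GC fraction
(default 0.5, default width 7 bp, with 25 bp used for flank
analyses). `generate_coding_set` emulates start-aligned genes: an
i.i.d. UTR, a forced ATG, then codons drawn i.i.d. from a usage table
(default uniform over the 61 sense codons).

What these generators do *not* emulate: phylogenetic correlation
between sites, genomic GC heterogeneity and isochores, real codon-usage
bias, dinucleotide autocorrelation in non-coding DNA, and binding-site
evolution. Passing tests therefore demonstrate that the computation
and inference machinery behaves correctly under known positional
frequency structure — not that any particular genome shows a given
effect size. Genome-scale conclusions require the user's own aligned
sequence data, which every reader accepts via the three dialects.

The default analysis sizes (200 genes × 100 codons for the phase scan;
100 bootstrap sets of 10 genes; 200 null replicates on a 1000-gene
pool; n = 5000 sites for conservation recovery) were chosen as the
smallest sets where the phase and conservation effects are stable
across seeds.

## Numerical choices

* Entropy columns are validated (non-negative, sum 1 ± 1e-9); IC is
  clipped to [0, log2 k] after a 1e-9 tolerance check.
* The classic small-sample bias correction `e(n) = (k−1)/(2 ln2 · n)`
  is available but off by default; the plain equations are the
  contract, and all reported quantities use them.
* Degenerate statistics (zero variance in every group) return t = 0,
  p = 1 and F = 0, p = 1 rather than NaN.
* Rendering is deterministic: fixed SVG hash salt, timestamps
  suppressed in SVG/PDF metadata, glyphs drawn as stretched font paths
  (DejaVu Sans bold), bars behind letters with a 0.7 pt black outline
  so near-white bars stay visible. Letter stacks order letters by
  ascending frequency, most frequent on top, height `p · IC`.
* Bar geometry (`bar_start`, `bar_increment`) is plain configuration;
  defaults place each bar midway between adjacent letter columns and
  suit ~20 bp sequences.

## Known limitations

* The TRX scale treats linkages independently; higher-order (trimer or
  tetramer) flexibility effects are out of scope.
* Linkage IC has a composition floor: because the 9 states partition
  the 16 dimers unevenly, even i.i.d. random DNA shows nonzero linkage
  IC (≈ 0.058 normalized bits at uniform composition, more for skewed
  compositions). Comparisons should always be made against a
  composition-matched background, as the codon-context scan does.
* The bootstrap ANOVA is anti-conservative on small gene pools (see
  above).
* Center alignment is positional only; no similarity-based alignment
  is performed anywhere.
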