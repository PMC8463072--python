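# Methods

## Quantification model

The package models a two-level TMT SPS-MS3 quantification: MS1 precursor
intensity carries the protein group's total signal across the multiplexed
set, and MS3 reporter intensities carry its split across channels.  The
summed MS1 intensity of each protein group is allocated to channels by the
fractional reporter intensities,

    I[p, s] = MS1[p] · r[p, s] / Σ_j r[p, j],

which conserves the MS1 total exactly and assigns zero to channels with
zero reporters.  Records with positive MS1 but an all-zero reporter vector
cannot be allocated; they are dropped and counted, never imputed — any
imputation would invent signal.

Copies per cell come from the histone proteomic ruler: histones are
stoichiometric with DNA, so the summed histone MS signal in a sample is
taken to represent the cell's DNA mass `m_DNA` and every protein's
intensity-per-Dalton is scaled by the same factor,

    copies[p, s] = (I[p, s] / MW_p) · (m_DNA · N_A) / Σ_{h ∈ histones} I[h, s].

Consequences of this form, which the tests verify exactly: histone mass per
cell equals `m_DNA` in every sample (conservation); the estimator is a
ratio and hence invariant to any per-sample rescaling of intensities
(instrument response, loading); and histones act simultaneously as anchors
and as quantified proteins.  Per-cell protein content is
`Σ_p copies · MW_p / N_A`, reported in picograms.

**DNA mass per cell** defaults to 5.52 pg — a diploid mouse genome,
~2 × 2.7 Gbp at ~615 g/mol per base pair.  The absolute scale of every copy
number is proportional to this constant, so it is exposed in every API and
recorded in run metadata.  No ploidy or cell-cycle correction is applied.
**Histone selection** is by case-insensitive gene-symbol match against a
shipped list of mouse core and linker histone symbols
(`data/histone_genes_mouse.txt`), overridable by file; symbol matching is
auditable, and the chosen set is part of the absolute scale.

## Filters and replicate QC

Rows flagged contaminant, reverse, or only-identified-by-site are removed,
as are rows with fewer than two razor+unique peptides (MaxQuant's
"Razor + unique peptides" column by default; a switch selects
"Unique peptides" since the two readings of "unique and razor" differ).
The replicate QC formalises an exclusion judgement usually made by eye:
within each population with at least three replicates, a replicate is
flagged when its protein content deviates from the leave-one-out median of
its population by at least a threshold, default 0.15.  The threshold is
inclusive (≥), with a 1e-9 relative tolerance so that a deviation of
exactly 15% is flagged regardless of float round-off.  Populations with
fewer than three replicates are skipped with a warning because the
leave-one-out median is unstable there.

## Differential expression

Copy numbers are variance-stabilised as `log2(x + 1)`; the pseudocount is
exposed (copy numbers of detected proteins are ≫ 1, so the choice matters
only near zero).  For a two-population contrast the per-protein pooled
variance `s²` with `d = n_a + n_b − 2` degrees of freedom is shrunk toward
a prior variance via the standard hierarchical model in which `s²` follows
a scaled F distribution around `s0²` with prior degrees of freedom `d0`.
The prior is estimated by moment matching on log variances: with
`e = log s² − ψ(d/2) + log(d/2)`, solve `ψ′(d0/2) = Var(e) − ψ′(d/2)` by
Newton inversion of the trigamma function and set
`s0² = exp(mean(e) + ψ(d0/2) − log(d0/2))`.  When the spread of log
variances does not exceed its expectation under equal true variances,
`d0 = ∞` (all variances fixed at `s0²`, normal reference); `d0 = 0`
recovers the ordinary pooled t test.  Matrices with fewer than 10 genes
fall back to `d0 = 0` with a warning.  The moderated statistic
`t = Δmean / √(s̃² (1/n_a + 1/n_b))` with
`s̃² = (d0 s0² + d s²)/(d0 + d)` is referred to a t distribution with
`d0 + d` degrees of freedom.

Significance classes follow the fold-change-distribution convention: with
`m` and `sd` the median and standard deviation of the contrast's log2 fold
changes, `**` requires `p < 10⁻³` and `|log2fc − m| ≥ 1·sd`, `***` requires
`p < 10⁻⁴` and `|log2fc − m| ≥ 1.5·sd`, and the ORA candidate sets use
`p < 10⁻³` with the 1.5·sd cut, split by direction.  The "±" is read as
two symmetric cutoffs about the median — the only reading under which the
downward rule is coherent.  These rules gate on the moderated p-value, not
the q-value; q-values are attached for protein-level FDR.  `sd = 0`
suppresses all non-ns labels with a warning.

Proteins with zero copies in every sample of one population but detected in
the other are partitioned out as *exclusive* before fitting, and reported
with an exclusivity label instead of a fold change: a pseudocount fold
change against an all-zero group is an artefact of the pseudocount, and
leaving such proteins in would also inflate the fold-change sd that the
thresholds depend on.  For ORA, exclusives are unioned with the significant
candidates of their direction (detection = nonzero copies in at least half
of that population's retained replicates; exposed parameter).

Storey q-values estimate π0 over a λ grid (default 0.05…0.95 step 0.05)
with a cubic smoothing spline evaluated at the largest λ, clipped to
(0, 1]; a single-λ grid uses the raw estimate, and fewer than 20 p-values
fall back to π0 = 1, i.e. Benjamini–Hochberg.  Welch's unequal-variance t
test (Welch–Satterthwaite df) is used for aggregate quantities such as
gene-set copy sums, where per-set variance moderation across a handful of
sums would be meaningless.

## Overrepresentation analysis

One-sided hypergeometric upper-tail p per gene set — identical to
one-sided Fisher's exact on the 2×2 table, a cross-check the tests
enforce — with the background defined as the union of proteins detected in
either contrasted population.  Hits outside the background are dropped with
a warning and sets are intersected with the background before testing.
Across sets, Benjamini–Hochberg FDR at 0.05 is the reporting cut.  Term
databases are user-supplied GMT files; no annotation service is queried,
and term-clustering (as in DAVID's functional annotation clustering) is
out of scope — flat ORA rows are emitted.

## Landscape summaries

PCA operates on `log2(x + 1)` copy numbers of proteins detected in every
sample (complete cases), per-protein mean-centred, via SVD with a
deterministic sign convention (largest-magnitude loading positive).
Population correlations are Pearson r on `log10(median copies + 1)` over
proteins detected in both populations of a pair; degenerate pairs are
reported missing (NaN), never coerced to 0.  Raw copies span ~6 orders of
magnitude, so both transforms are defaults rather than options of
convenience; both are switchable, and correlation/variance-fraction values
on real data should be read as transform-dependent.  The "top fraction of
the proteome" summary ranks proteins by mass (copies × MW; a copies basis
is available), takes the smallest prefix whose cumulative mass reaches the
requested fraction of the sample total (the crossing protein is included),
and partitions it into the supplied non-overlapping categories plus a
remainder.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis assumes:
five populations with pre-QC replicate counts 6/6/4/4/4 across 24 channels;
~8000 protein groups with log10 baseline abundance N(4.0, 1.0); ~30 histone
rows drawn at the high-abundance tail (baseline + 1.5 sd, so the anchors
dominate as in real cells) and rescaled once so their summed mass equals
the DNA mass — making the noise-free pipeline an exact round trip;
category-level planted log2 fold changes; population-specific absence
(all-zero reporters in one population, 5% of proteins); decoy and
low-peptide rows (40/40/60); per-channel acquisition scale factors (the
ruler must cancel them); and multiplicative log-normal reporter noise with
a mean of one and CV 0.10.  The per-channel CV of the real acquisition is
not published; 0.10 is a generator choice in the plausible range for
SPS-MS3 reporter ratios, not a claim about the study.  Noise is applied to
reporters only, after MS1 is formed as the noise-free channel sum, so MS1
reallocation is a genuine estimation problem.  The planted content-outlier
multiplier acts on measured protein content: since histone mass is pinned
by the ruler, non-histone copies are scaled by `(m − h)/(1 − h)` with `h`
the histone mass fraction.

Not emulated: spectrum-level effects (co-isolation interference, isotope
impurity), peptide-to-protein roll-up, missing-not-at-random dropout,
between-replicate biological variability beyond reporter noise, and
correlated abundance structure across proteins.  Passing tests therefore
demonstrate correctness of the arithmetic and calibration of the statistics
under the stated model — not robustness to interference or biological
heterogeneity.

One normalisation property worth knowing: because copy numbers are ratios
to the per-sample histone sum, reporter noise on the histones induces a
small per-sample shift shared by all proteins.  In a null contrast this
shifts every fold change coherently by a few hundredths of a log2 unit —
negligible against the significance thresholds, but detectable by a
Kolmogorov–Smirnov uniformity test at 5000 proteins.  The null-calibration
test therefore draws null matrices from the hierarchical variance model
directly; the shift is a property of ratio normalisation, not of the
moderated statistic.

## Problem sizes and numerics

The test suite and acceptance script run the noise-free round trip at the
full 8000-protein design and the stochastic recovery checks at 1000–5000
proteins over 3–10 seeds each — sizes at which the measured quantities are
stable to well within the asserted bands while the whole suite stays fast.
Conservation and oracle-equivalence checks assert at 1e-9…1e-12 relative
error; trigamma inversion runs Newton to 1e-10 relative tolerance; PCA
sign, mergesort-based rankings and seeded generators make every output
bit-reproducible for a given configuration.
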