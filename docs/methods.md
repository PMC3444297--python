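# Methods

## The pooled design and its statistical problem

The package targets expression data from a fully pooled bead-array design:
four diet conditions (NCD, HFD, NCD+BB, HFD+BB), one pooled RNA sample per
condition, one array per sample.  Pooling collapses mouse-to-mouse
variance by construction, so the only replication left is technical — the
~30 physical beads per probe on each array, which the scanner software
summarizes into a per-probe mean signal, bead variance (or standard
error), bead count and detection p-value.  Every statistic in this package
is built on those summaries.

## The pooled-variance F test

For probe *i* with group means $\bar x_{ig}$, bead variances $s^2_{ig}$
and bead counts $n_{ig}$ over $k$ groups:

* between-treatment variance: the sample variance (denominator $k-1$) of
  the $k$ group means;
* within-treatment variance: the mean over groups of $s^2_{ig}/n_{ig}$,
  i.e. the estimated variance of each group **mean** — chosen so numerator
  and denominator are variances of the same quantity (a group mean).  A
  switch (`variance_of_mean=False`) uses the unscaled bead variance
  instead, for the literal bead-population reading;
* $F$ = between / within, referred to $F(\mathrm{df}_1, \mathrm{df}_2)$,
  upper tail.

**Degrees of freedom.** The design prescription "set the degrees of
freedom to the average number of beads" is ambiguous for a two-df
distribution.  The default resolves it conventionally:
$\mathrm{df}_1 = k-1$ (the numerator is a variance of $k$ means) and
$\mathrm{df}_2$ = the probe's average bead count, rounded half-to-even
(fractional dfs are allowed via `integer_df=False`).  A literal reading —
both dfs equal to the average bead count — is available via
`df1_rule="average-beads"`.  Neither convention is exact: the true
denominator df of an average of four bead-sample variances is larger than
one bead count (≈ 4(n−1) for normal beads, less for heavy-tailed
intensities), so the default test is somewhat conservative in the far
tail.  The null simulations below measure, rather than assume, the
consequence.

**Scale.** Testing defaults to the log2 scale: group means are
log2(signal + offset) (or a quantile-normalized matrix supplied by the
caller), and bead variances are mapped by the delta method,
$\mathrm{var}_{\log_2} = \mathrm{var} / ((x+\mathrm{offset})^2 \ln^2 2)$.
Raw-scale testing (`scale="raw"`) uses the summaries as-is.  Bead
variances are never rescaled by the quantile-normalization map: the map is
monotone and near-affine locally, and the variances are the scanner's
bead-level estimates, which the normalization does not refine.

**Degenerate probes.** Within-variance exactly 0 with equal means gives
p = 1; with unequal means it gives p = 0 and a `degenerate` flag rather
than a division error.

**Multiplicity.** Bonferroni over the probes actually tested (not a fixed
platform-size constant), `min(1, m·p)`.  Both the raw-p and the
Bonferroni-p probe counts are first-class outputs, because screening
pipelines of this kind have used either as the "significant" list.

## Normalization and QC

Quantile normalization maps every column onto the row-mean of the sorted
columns.  Ties within a column receive the mean of the reference values
over the tied rank positions, which keeps the operation deterministic and
preserves column sums; on tie-free input the operation is idempotent and
rank-preserving (both property-tested).  The order of operations is log2
first, then quantile normalization, matching QC that is defined on log2
values.  QC itself is numeric by contract: MA statistics
(M = difference, A = mean of two log2 columns) for every array pair, and a
group × group distance matrix (1 − Pearson correlation) for array-level
clustering; plot rendering is left to the caller.

## Contrasts and screens

Contrasts are log2-ratio columns, lr = mean log2(numerator) − mean
log2(denominator).  Because contrasts are differences, any contrast is
derivable from two others sharing a reference group
(lr(C/B) = lr(C/A) − lr(B/A)); `ContrastTable.derive` implements the
identity, which is exact to floating-point precision and property-tested
over all group triples.

Screens select probes passing a p gate (raw or Bonferroni column, level
configurable, default raw p < 0.05) **and** a directional log-ratio
cutoff.  The conventional "≥1.3-fold" cutoff is implemented as
|lr| ≥ 0.4 log2 units — the quoted operative value, kept as stated even
though log2(1.3) = 0.3785.  The zero-cutoff variant is a strict sign test
(lr = 0 never counts as regulated).  Opposite-direction cross-screens
intersect a base screen with probes whose comparison-contrast ratio has
the opposite sign at the chosen cutoff; results are antitone in the
cutoff (tested).  Probe lists are collapsed to unique gene symbols
through the probe annotation, with unannotated probes counted separately
as "unknown" so that list-size bookkeeping stays transparent.

## Overrepresentation statistics

For a list of $n$ genes from a universe of $N$, a set with $R$ members in
the universe and overlap $r$:

* exact hypergeometric upper tail $P(X \ge r)$ (EASE-style $r-1$ variant
  available as an option; the plain tail is the default),
* fold enrichment $(r/n)/(R/N)$,
* z-score $(r - nR/N) / \sqrt{n \frac RN (1-\frac RN)(1-\frac{n-1}{N-1})}$
  — the hypergeometric mean/variance standardization, no continuity
  correction.

The three statistics agree in sign direction
(fold > 1 ⇔ z > 0 ⇔ r > nR/N), which is asserted as an invariant.  The
default universe is all annotated probes of the analyzed matrix collapsed
to unique genes; any explicit background list can be supplied instead.
No multiplicity correction is applied across sets by default (reported
enrichment p-values are raw); reporting thresholds default to overlap
≥ 3, z > 2, p ≤ 0.05.

## Phenotype statistics

Group summaries are mean ± SEM with the non-missing n per metric.  The
Mann–Whitney U test enumerates all $\binom{n_a+n_b}{n_a}$ labelings of the
pooled values for combined n ≤ 20 (average ranks under ties, so the
enumeration stays exact), reporting U = min(U₁, U₂) and a two-sided p as
the doubled lower tail capped at 1 (a both-tails variant is available; the
two coincide for the symmetric U null).  Larger samples fall back to the
tie-corrected normal approximation and are flagged.  Diet contrasts follow
the two-stage scheme: the four groups pooled by a factor (fat content or
supplement) are tested first; each diet against its own control second,
Bonferroni-corrected over that two-test family; absolute and percent
mean differences accompany the tests.  Diet energy arithmetic uses
Atwater factors 4/4/9 kcal/g on per-100 g macronutrient compositions —
the convention under which the built-in diet table reproduces its printed
3.8 / 4.7 kcal/g densities and 10% / 45% fat energy shares.

## The synthetic-data generator

**Bead summaries.** Per probe, a baseline log2 level ~ Normal(8, 1.5);
per probe × group, a bead count max(5, Poisson(30)); per bead, intensity
= 2^(baseline + planted shift + Normal(0, σ)) with σ = 0.5 log2 units by
default — bead noise is normal on the log scale (lognormal intensities),
the simplest model consistent with log-scale testing.  Summaries (mean,
two-pass sample variance, count) are computed from the simulated beads
exactly as a scanner would.  Detection p-values are Beta(1, 50) for
expressed probes and Uniform(0, 1) for an optional unexpressed fraction.
The planted-effect table maps probes to per-group log2 shifts; the
built-in 13-probe crystallin block uses the lens-crystallin
induction-and-partial-reversion pattern (strong upward shifts in HFD,
smaller in HFD+BB and NCD+BB, zero in NCD).  Identical seeds give
bit-identical output.

**Phenotypes.** 24 mice in four groups of six.  End-of-study metrics
(systolic blood pressure, blood glucose, serum free fatty acids) are
normal draws around the built-in design group means with SD = SEM·√n from
the design summaries; per-metric missingness reproduces the design's
per-metric n.  Weekly weights share a common slope (0.6 g/week from a
20 g start) until week 5, after which high-fat groups add 0.225 g/week —
sized so the final weight-gain difference is ≈ +1.8 g (+25%).  Cage
intake metrics are drawn per cage of two and attributed to both cage
mates.  A `noiseless()` config zeroes all spread for exact-mean checks.

**What the generator does not model:** probe cross-hybridization, spatial
array artifacts, heavy-tailed bead noise, batch effects, or
mouse-to-mouse variance within a pool (pooling removes it by design).
Passing tests on this generator therefore demonstrate the pipeline's
internal correctness and its behavior under the idealized noise model,
not robustness to real-array artifacts.

## Problem sizes and numerical choices

Simulation-based checks use 5,000-probe matrices (null calibration and
planted recovery), 100 replicate null runs for the family-wise error
check, and 200 replicate phenotype simulations for the power check —
sizes at which the measured proportions are stable to a percent or two
while the whole suite stays fast.  Null calibration under the default df
convention measures a type-I rate of ≈ 0.042–0.045 at nominal 0.05
(slightly conservative, as the df analysis predicts) and raw-p uniformity
passing a KS test at the 0.01 level; these are measured outcomes, not
assumptions.  Ties in ranked outputs are broken deterministically
(p ascending, then F descending, then probe id).  All result tables are
written with 12 significant digits so write→read round trips are lossless
in practice, and pipeline stages write via temp-file-and-rename so
interrupted runs leave no partial tables.

## Known limitations

* The F test's p-values are screening devices; with one pooled array per
  group they cannot be interpreted as calibrated biological inference.
* The exact Mann–Whitney path enumerates up to combined n = 20
  (C(20,10) ≈ 184k labelings); beyond that the normal approximation is
  used even though "exact" may be requested implicitly.
* Gene-set content is entirely user-supplied (GMT); no ontology hierarchy
  or term-specificity filtering is performed — a generic set-size filter
  stands in.
* Probe annotation is a static table; no live reannotation against
  current databases.
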