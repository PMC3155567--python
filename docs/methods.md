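# Methods

## The design being modelled

The pipeline analyses a pooled two-color microarray design for detecting
small sex differences in human liver expression.  Each sex's 112 RNA
samples are randomly partitioned into 8 pools of 14; a second, independent
partition of the same individuals yields 8 more pools per sex.  Pool M*i*
is hybridised against pool F*i* on a two-color array (16 arrays total),
with the dye assignment swapped on alternate arrays so dye-specific
intensity bias cancels across the replicate set.  Pooling equal RNA masses
averages biological variability before measurement, so the per-array
male/female ratio estimates the sex effect with variance dominated by
technical noise plus pool-composition sampling.

## Synthetic data generator

`generate_cohort` plants per-gene log10 sex effects on a lognormal
expression baseline:

| parameter | default | rationale |
|---|---|---|
| `n_male`, `n_female` | 112 / 112 | the design's cohort size |
| `frac_biased` | 0.05 | a few percent of the transcriptome is detectably sex-biased in liver |
| `frac_female_biased_of_biased` | 0.70 | the observed female-biased excess |
| `effect_range_log10` | [log10 1.15, log10 2] | sex effects in liver are mostly below 2-fold; 1.15 is the calling floor |
| `indiv_sd_log10` | 0.15 | moderate inter-individual biological scatter (≈1.4-fold CV) |
| baseline mean/sd (log10) | 2.5 / 0.5 | fluorescence-scale intensities spanning ~1.5 orders of magnitude |

Half of each effect is added to males and subtracted from females on the
log10 scale, keeping the grand mean sex-invariant.  Pool signal is the
arithmetic mean of members' linear-scale expression (equal RNA mass per
member), not a geometric mean.

`simulate_arrays` produces channel intensities as
`pool signal × dye-bias(mean intensity) × lognormal noise + background`.
The dye bias is a smooth monotone sigmoid of log10 mean intensity attached
to channel A (amplitude 0.15, centre 2.5, width 0.5 by default), identical
across arrays and therefore sign-flipped by dye orientation — exactly the
structure LOWESS normalization is meant to remove.  The per-channel noise
sd (log10) defaults to 0.0617, calibrated so that the mean replicate
scatter of normalized log10 ratios across the 16 arrays is ≈0.0896 — the
one dispersion the design publishes — once pool-composition variation
(individual sd 0.15, pools of 14) and the additive background (30
fluorescence units) are included.  Per-array across-probe scatter then
falls near 0.10, inside the plausible 0.06–0.12 band.

What the generator does *not* emulate: probe-level cross-hybridization
(e.g. Y-chromosome probes picking up autosomal transcripts), age
structure, spatial array artifacts, and heavy-tailed outlier noise.
Passing tests therefore demonstrate correctness of the statistical
machinery under a clean noise model, not robustness to every failure mode
of real arrays.

`generate_codon_pairs` mutates a random stop-free ancestor with separately
counted synonymous and non-synonymous single-nucleotide substitutions,
with counts inverted through the Jukes–Cantor map so the NG86 estimates
centre near the requested dS (default 0.35, a typical human–mouse
synonymous divergence) and dN/dS target.

## Normalization and replicate combination

Per array: the log10 ratio is orientation-corrected to male/female, a
LOWESS fit (span 0.4, matching the broad smoothness of dye-bias trends)
of ratio vs mean log10 intensity is subtracted, then ratios are
median-centred.  Probes with both channels at or below background are set
missing; probes missing on more than 2 of 16 arrays are excluded from
calling.

The replicate-combination error model is an intensity-vs-dispersion fit:
each probe's replicate sd is regressed (LOWESS, log scale) on its mean
intensity across all probes, and the fitted curve evaluated per
probe/array is the error estimate.  This borrows strength across probes of
similar intensity, the same stabilisation idea as commercial array error
models, with a fully documented formula.  Replicates are combined by
inverse-variance weighting (w = 1/error²), standard error √(1/Σw), and a
two-sided normal p-value for mean log ratio = 0.

The power analysis uses a two-sided one-sample t-test at α = 0.05: the
smallest fold change whose noncentrality √n·log10(FC)/sd reaches the
target power under the noncentral t with df = n−1.  At sd 0.0896, n = 16,
power 0.8 this gives 1.167 (a stricter α = 0.005 would give ≈1.24; the
published sensitivity is consistent only with the 0.05 convention, which
is why the module defaults to it).

## Calling, FDRs, and their calibration

Calling combines |FC| > 1.15, p < 0.005, and composite score ≥ 14 (13, 12
as relaxed tiers; the tiers are nested by construction).  Ratios exactly
at 1 count toward neither direction; missing arrays shrink the score's
reference count.  Gene-level deduplication keeps, per gene symbol and
direction, the probe with the highest composite score (ties: lower p,
then probe id); opposite-direction probes of one gene are all retained;
probes hitting >3 genomic sites without an mRNA-level match are dropped;
multi-hit probes stay in the calls but are excluded from chromosome
analyses.

The binomial apparent FDR uses the **one-sided** tail Σ<sub>k≥14</sub>
C(16,k)/2¹⁶ and rounds the expected count to an integer before forming
the ratio; both choices are needed to reproduce the arithmetic
10/1295 = 0.77% and 24/2575 = 0.93% exactly (a two-sided tail would give
an expected count of ≈20).

**Calibration caveat.**  The apparent FDR is *not* an unbiased estimate of
the realised false-call fraction, and the package's simulations quantify
this.  Under the null, a single replicate mean drives all three criteria:
a probe whose 16-array mean drifts past the fold-change threshold has, for
that very reason, a high probability of 14/16 sign agreement and a small
p-value.  The binomial estimate multiplies the marginal probabilities
instead, so it understates the joint null rate by one to two orders of
magnitude under independent Gaussian array noise (simulations here show
~10–100× depending on tail weight), and a biological contribution makes it
worse: with 112 individuals per sex, the realised cohort mean difference
of a truly null gene has sd ≈0.02 (log10), shifts all 16 arrays
coherently, and produces genuine — but sex-unrelated — consistent signals.
The acceptance check asserting empirical-FDR agreement with the binomial
estimate within 2× therefore fails under this generator, and we report it
as failing rather than tuning the noise model to hide the effect.  The
apparent FDR remains what it is: a lower bound useful for comparing
threshold choices.

For the same reason, the composite-score null-calibration check runs on
**technical-null arrays** (no sex effects and no inter-individual
variation): the Binomial(16, ½) reference models array measurement noise
only, and that is the null under which the score distribution matches
max(K, 16−K) (goodness-of-fit p ≈ 0.23 at 50,000 probes).  With
biological variation included the score distribution is over-dispersed,
as expected from the argument above.

## Chromosome and cross-cohort analyses

Per-chromosome enrichment is a 2×2 chi-square (chromosome vs rest × male
vs female), no continuity correction, switching to Fisher's exact test
when an expected cell drops below 5; a goodness-of-fit mode against the
genome-wide split is exposed as well because the published description
("compared to the overall distribution") does not pin the construction
down — neither form reconstructs the published chromosome-19 p-value from
printed counts, so both are provided.  X-escape concordance counts panel
genes with female-biased direction at a required composite score.

Cross-cohort validation uses Welch's unequal-variance t-test (the
published description says only "two-tail t-test"; Welch is the safer
default for post-mortem cohorts of unequal size and variance), means on
the linear scale before the log2 ratio, and an explicit user-supplied
exclusion list for discordant genes rather than an automatic rule (no
threshold is published).  Age-restricted analyses are expressed by
filtering columns before calling, not by a dedicated operation.  The
16-vs-16 subsampling permutation draws disjoint subsample/remainder
partitions each round; note that on a single finite cohort the rounds
share the (nearly constant) remainder side, so the null mean correlation
has cohort-level variability of order 1/√n_genes — tests average over
cohorts.

## Evolutionary rates

dN/dS uses Nei–Gojobori counting: per-codon synonymous site fractions are
computed over single-nucleotide changes that do not create stop codons
(nonsense changes disregarded, so each codon still contributes 3 sites);
observed differences at multi-substitution codons are averaged with equal
weight over substitution orderings whose intermediates are not stops
(falling back to all orderings if none qualify); both proportions receive
the Jukes–Cantor correction d = −¾ ln(1 − 4p/3), undefined at p ≥ ¾
(records flagged invalid).  Only the universal code is supported;
ambiguous codons are skipped and counted.  This counting estimator stands
in for codon-model maximum likelihood; a precomputed-ratio table
(`gene_id, dnds`) can be substituted bit-for-bit where ML output is
available.  Per-gene ratios are medians over accession-level ratios.

The difference-of-medians permutation test is one-sided (Nd counts
resampled differences ≥ observed) with p = Nd/n_perm and no +1
correction, matching the published definition.  Whether the resampling
background is the union of the two tested groups or all orthologs is left
to the caller as an explicit argument, since the published description is
ambiguous.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 3,000–20,000 genes (112+112
individuals) and 50,000 probes for the score-calibration check — sizes at
which every Monte-Carlo tolerance in the suite has comfortable margin
while the whole suite runs in well under a minute of simulation time.
LOWESS uses a `delta` shortcut above 5,000 points (pure speed; identical
to within interpolation error).  The power solver brackets the
noncentrality parameter and uses Brent root-finding with 1e-10 tolerance.
Dedup tie-breaks and the ratio-exactly-1 convention are documented
choices where the published description is silent.

## Known limitations

- The apparent-FDR calibration gap described above is inherent to the
  statistic, not fixable by tuning; treat apparent FDRs as comparative,
  not absolute.
- NG86 counting underestimates dN/dS under strong codon usage or
  transition/transversion bias relative to ML estimators.
- The simulator's Gaussian log-noise has lighter tails than real array
  data; outlier-driven artifacts (cross-hybridization, spatial defects)
  are out of scope.
- Chromosome analyses require externally supplied probe annotations;
  probe-to-genome mapping is consumed, never computed.
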