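# Methods

`kogrowth` implements the computational chain of a genome-wide single-gene
knockout growth screen in *Escherichia coli*-like bacteria: estimating
exponential growth rates from plate-reader OD600 curves, classifying gene
fitness contributions, comparing growth and wild-type expression between a
rich and a poor medium, and testing for chromosomal periodicity of both
quantities on the circular genome. This note records the models, the
defaults, the numerical choices, and the places where the design was
genuinely open.

## Growth-rate estimation

The rate between two consecutive readings is

    mu_i = ln(C_{i+1} / C_i) / (t_{i+1} - t_i)

on blank-corrected ODs `C`. The reported exponential rate of a curve is the
mean of the best window of five consecutive interval rates. "Best" is a
two-objective notion (large mean, small scatter) that has no unique
resolution; the package's rule is: take the maximal window mean; among
windows within 5% of that maximum, take the minimal standard deviation;
break remaining ties by the earliest window. The 5% slack is the point of
the rule — without it the SD criterion never fires on real (noisy) data.
The rule is verified against an exhaustive search over all windows on every
tested curve.

Blank correction subtracts a per-plate blank (estimated from wells mapped
to strain `BLANK` at t = 0); intervals whose endpoints sit at or below a
positivity floor of 0.003 OD above blank are masked, because the log of a
blank-level reading is noise. A curve with no valid 5-window, or whose best
window mean is non-positive, is flagged no-growth and excluded from
aggregation (its count is retained). The growth maximum is the maximal
blank-corrected reading, unsmoothed.

Interval rates are exact on exponentials for any time grid (the log-ratio
telescopes), which pins the estimator's error entirely on model departure
and noise. On logistic curves the estimate is biased low by roughly the
mean OD/K over the selected window; with 15–30-min sampling from a low
inoculum the window sits at OD ≪ K and the bias is negligible. This matters
for the well-location diagnostic below: at coarse sampling the window
climbs into the logistic bend and a carrying-capacity bias leaks into the
rate estimate.

The well-location diagnostic orders wells by a serpentine index
(A1..A12, B12..B1, ...), a fixed documented convention, and reports the
Spearman trend of per-well mean rate and per-well mean growth maximum. The
expected signature of a location artefact on plates is a strong maximum
trend with no rate trend.

## Fitness classes and enrichment

Per medium, knockout rates are placed against the box-plot fences of their
own distribution: Q1/Q3 by linear interpolation (the "type 7" quantile
convention), fences at 1.5·IQR beyond the quartiles. Class semantics invert
the rate, because a strain that grows faster *without* a gene reveals a
gene that was costly: above the upper fence → `very_negative` gene, between
Q3 and the upper fence → `negative`, within [Q1, Q3] → `neutral`, between
the lower fence and Q1 → `positive`, below the lower fence →
`very_positive`. Boundary values are assigned inward (a rate exactly at a
quartile is neutral). With interpolated quantiles and distinct values the
neutral class holds every rank in [ceil(1+(n−1)/4), floor(1+3(n−1)/4)] —
slightly under half the strains, not "at least half"; the property test
asserts the exact rank-count identity.

Enrichment of a selected gene set is a one-sided binomial test per flat
functional-category code: `p = P(X ≥ x)`, `X ~ Binomial(n, m/M)`, with
Bonferroni correction over the categories tested. The background `M` is the
sampling frame of the selection: all annotated non-essential genes for
fitness-class selections (the knockout library), all annotated genes for
expression-based selections.

The replicate-level re-evaluation demotes a non-neutral call to neutral
unless a two-sided one-sample t-test of the strain's replicate rates
against the medium's median rate rejects at alpha = 0.05. The specific test
is a declared convention (the screening literature describes the filtering
step but not the test); strains with fewer than two replicates are exempt
and flagged rather than silently demoted.

## Differential analysis (rank product)

Expression tables (log10 RPKM, replicate columns) are globally normalized
by a per-dataset additive shift bringing every dataset's median to the mean
of the input medians; a constant shift preserves within-dataset ranks
exactly.

Differential items between two media use the rank product. The comparison
columns are all R_A × R_B unpaired replicate pairs (fold difference A − B
in log space; for growth, differences of replicate rates), ranked per
column with mid-ranks on ties, rank 1 = strongest change in the tested
direction. The statistic is the geometric mean of an item's ranks; both
directions are tested.

Significance is by permutation, and the null construction is the one
numerical decision that matters here: the null permutes each **raw
replicate column** across items and recomputes the fold-difference ranks,
rather than shuffling the derived comparison columns independently. The
derived columns share replicates (columns (i, j) and (i, j′) share A_i), so
independently shuffling them destroys that coupling and produces a null
whose RPs are systematically less extreme than observed RPs even with no
effect — the resulting p-values are U-shaped rather than uniform.
Replicate-level permutation preserves the coupling; pooled null p-values
pass a Kolmogorov–Smirnov uniformity check, and for a single shared
replicate the two constructions coincide (which is why the exhaustive
36-table enumeration oracle at G = 3, K = 2 applies unchanged). The
permutation p is `(#{null RP ≤ RP_g} + 1) / (n_perm·G + 1)`.

Two FDR measures are emitted: the rank product's native pfp (expected false
positives divided by the item's rank, monotonized step-up in p) as the
primary `q`, and Benjamini–Hochberg on the permutation p-values as a
secondary column so the choice is auditable. Differential calls take the
union of both directions at q < 0.05.

## Growth–expression association

Knockout rates join wild-type expression on gene id (the strain id *is* the
deleted gene). The gene-level statistic is the Spearman correlation per
medium on strain means. Its significance is backed by a randomization test:
each column is shuffled independently (1,000 shuffles by default, separate
seed streams per column) and the two-sided empirical p uses the add-one
convention `(#{|rho_null| ≥ |rho_obs|} + 1)/(n_shuffles + 1)`, which never
reports an exact zero. Category-level structure is summarized by the
Spearman correlation across the mean rate/mean expression of categories
with more than 30 genes, plus within-category correlations.

## Chromosomal periodicity

Per-gene values become a positional signal on the circular genome: one
anchor per kilobase, each anchor averaging the genes whose midpoint falls
in the half-open window [a, a+100 kb) — left-anchored windows, a declared
convention (centered windows shift only the fitted phase). Gene midpoints
are circular (genes wrapping the origin are handled modulo L). Three modes
serve the three analyses: `essential_zero` includes essential genes at
value 0 (their knockout is lethal — zero growth), `nonessential_only`
drops them, `density` counts genes per window. Empty windows are filled
with the global mean of non-empty windows, which is neutral under the
mean-subtraction that precedes the transform; this fill and the window
convention do not move the dominant harmonic on the tested signals (both
conventions were run on the synthetic harmonics).

The periodogram is the squared modulus of the DFT of the mean-subtracted,
smoothed series divided by N, at harmonics k = 1..N/2; the wavelength of
harmonic k is L/k. Any consistent power scaling gives the same g and
argmax; the chosen scaling is fixed by a Parseval identity test. The
dominant harmonic maximizes power with the full-genome harmonic k = 1
excluded by default (a peak at wavelength L reflects the genome's length,
not a repeating period); ties go to the smaller k. The 100-kb smoothing
multiplies harmonic k's amplitude by the Dirichlet factor
`sin(pi·k·W/L) / (W·sin(pi·k/L))`, asserted to 1e-6 in the tests.

Significance uses Fisher's exact g test: g = max ordinate / sum of
ordinates, with the closed-form null tail

    p = sum_{j=1..floor(1/g)} (-1)^(j-1) C(n, j) (1 - j g)^(n-1).

Terms are evaluated in log space; when the largest term exceeds ~1e13 the
alternating sum is no longer float-safe, which only happens deep in the
null bulk where the exact p is ≈ 1, so the test returns 1 there. The
implementation is calibrated against Monte-Carlo white noise (rejection at
p < 0.05 within [0.04, 0.06] over 2,000 simulations).

The dominant sinusoid `m + A·cos(2*pi*k*x/L + phi)` is the least-squares
fit, closed-form from the k-th Fourier coefficient (`A = 2|c_k|/N`,
`phi = arg c_k`, `m` = mean) because the harmonics are orthogonal on the
regular circular grid.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions of a genome-scale
knockout screen: a 4,632-kb circular genome; 4,200 genes with uniformly
scattered midpoints, 7.2% essential (≈3,900 knockouts); 19 flat category
codes with enzyme (`e`) the largest; a six-period positional cosine on
expression (amplitude 0.15 log10 RPKM) and, sign-reversed and phase-locked,
on knockout growth (amplitude 0.02 h⁻¹); two media (rich: mu_wt = 1.30 h⁻¹,
K = 1.00 OD; minimal: mu_wt = 0.50 h⁻¹, K = 0.60 OD); three replicates
sampled every 30 min for 24 h (49 points) from an inoculum of 0.01 OD over
a blank of 0.05.

The expression→growth coupling is
`mu_g = mu_wt − A_g·cos(theta_g) − beta·(E_g − baseline) + eps`, with
`eps ~ N(0, 0.03 h⁻¹)` and beta calibrated by bisection on the realized
Spearman correlation between mean expression and mu over the non-essential
genes (Spearman under mixed signal has no closed form). The default target
is −0.37; calibration converges to ±0.01 and errors out naming the feasible
range when the target is unreachable at |beta| ≤ 2. Because beta couples to
the full expression value, the noise-free limit with target −1 is exactly
monotone, and the growth and expression positional components are anti-phase
by construction.

Replicate-to-replicate rate variability is a free parameter (default
0.02 h⁻¹) — screens report means and standard errors, not this variance.
Plate curves are logistic with the well-location bias on the carrying
capacity only (`K_w = K + slope·serpentine index`), never on the rate, and
additive OD noise truncated at the blank (plate readers bottom out there).
Blank wells are emitted as flat blank-level series.

What the generator does **not** emulate: read-level RNA-seq counts (RPKM
noise is Gaussian in log space, not count-based), lag-phase and diauxic
structure in the curves, plate-edge evaporation, batch effects between
replicate days, and any real linkage between category, essentiality and
genome position (categories and essential flags are drawn independently of
position). A consequence of the last point: in `essential_zero` mode the
randomly placed zeros add window-level fluctuations of roughly
`mu_wt·sqrt(f(1−f)/n_window)` (~0.05 h⁻¹ at the defaults), which exceeds
the 0.02 h⁻¹ positional amplitude, so on synthetic data the whole-genome
mode is dominated by essential-placement noise and the planted harmonic is
demonstrated in `nonessential_only` mode. Passing tests therefore
demonstrate that the statistics recover
planted structure of the assumed shape at realistic sizes — not that real
screens are free of the artefacts the generator omits.

All stages draw from independent deterministic streams derived from the
config seed, so every output is byte-reproducible from the config.

## Problem sizes used in the checks

The bundled checks run the correlation-recovery analysis at the full screen
scale (4,200 genes, 10 seeds; 1,000-shuffle randomization), the Fisher-g
calibration at 2,000 white-noise signals of 400 bins, the rank-product
oracle at G = 3 with 10,000 permutations plus 20 null runs at G = 200, the
planted-category enrichment at 800 genes over 100 seeds, and the plate-bias
diagnostic at 285 strains × 3 replicates. The periodicity targets use the
full 4,632-bin genome.

## Known limitations

- The rank-product permutation null is Monte-Carlo; p-values have
  resolution 1/(n_perm·G + 1) and the pfp is an estimate, not an exact
  bound.
- Fisher's g assumes Gaussian white noise under the null; smoothed signals
  are autocorrelated, so g p-values on smoothed series are meaningful for
  ranking and for comparison across equally smoothed series rather than as
  exact tail probabilities. The calibration test runs on unsmoothed noise.
- The growth estimator reports no lag time or carrying-capacity fit; it is
  a windowed rate, by design.
- `reevaluate_by_replicates` treats the medium median as a fixed reference,
  ignoring its own sampling error (negligible at thousands of strains).
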