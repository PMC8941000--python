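# Methods

`ommnet` infers a signed, typed strain–strain interaction network for a
defined bacterial community — the use case it was written around is a
12-member synthetic mouse-gut consortium spanning five phyla — from four
kinds of routine measurements: OD600 growth curves, spent-medium (SM) growth
assays, untargeted metabolomics of culture supernatants, and qPCR-based
absolute abundances of mono-, pairwise and full-community cultures. This
note records the statistical definitions, the numerical choices, what the
synthetic twin does and does not emulate, and the known limitations.

## Growth phenotypes and spent-media inhibition

Each growth curve is blank-corrected (negative ODs clipped to zero) and
summarised by:

* **AUC** (OD·h): trapezoidal area over the full recorded window (default
  20 h, 10-min sampling). The trapezoid is exact for piecewise-linear
  curves; for smooth curves its truncation error is O(h²) (≈0.5% for an
  exponential sampled every 15 min).
* **Growth rate GR** (h⁻¹): the maximum slope of ln(OD) versus time over
  all contiguous windows of `window_points` readings (default 5) whose ODs
  all exceed `min_od` (default 0.02, ≈4 standard deviations of typical
  plate-reader noise). Rates are floored at zero; a curve with no eligible
  window reports 0 with a warning.
* **Rate class**: fast (GR > 1.5 h⁻¹), intermediate (1 < GR ≤ 1.5), slow
  (GR ≤ 1). Boundary values fall in the lower class because the upper
  classes are defined by strict inequalities.

Spent-medium inhibition of a consumer strain by a producer's SM is the
normalized factor

    d_AUC = (mean AUC_SM − mean AUC_fresh) / mean AUC_fresh,

computed from replicate means (three independent experiments in the
original assay design); d_AUC < −0.5 (strict) is flagged as strong
inhibition. The inhibition matrix is oriented rows = SM producer,
columns = growing strain, and every writer annotates this in a `#` header.

Supernatant pH is tracked as ΔpH_SM = pH_SM − pH_fresh (change caused by
growth in fresh medium) and ΔpH_DSM = pH_DSM − pH_SM (further change when a
second strain grows in the SM); the two deltas telescope back to the final
pH by construction.

Correlations (AUC vs rate, overlap vs inhibition, overlap vs phylogenetic
distance) default to Pearson's r with the two-sided t-distribution p-value
(n − 2 df); Spearman is available by flag. The linear coefficient is the
default because the quantities being correlated are reported on linear
scales; zero-variance inputs are rejected rather than returning NaN.

### Estimator bias — known limitation

The max-window log-linear estimator carries two opposite biases. On
noiseless logistic curves it *underestimates* μ by a factor ≈ (1 − N̄/K),
the saturation already incurred inside the fitted window; with a 0.02 OD
eligibility floor and low-plateau strains (K ≤ 0.5 OD) this reaches 5–7%.
On noisy curves it *overestimates*, because the maximum over many noisy
window slopes is upward-biased; for slow growers whose eligible windows sit
near the noise floor this can exceed the saturation bias several-fold.
Consequently rate classes are only guaranteed to be recovered on noiseless
curves, and validation of the estimator uses an eligibility floor of 0.005
OD (noiseless data carry no noise floor). Fitting a parametric logistic
model would remove both biases but is outside this package's scope, which
deliberately mirrors the window-based estimator common in batch-culture
work.

## Metabolomic depletion profiles

Feature intensities (integrated peak areas; positive- and negative-mode
features form one universe with mode-prefixed ids) are compared per strain
against fresh medium with a two-sided two-sample t-test, Welch's
unequal-variance form by default (Student's pooled form by flag). A feature
is **depleted** if p < α (default 0.05) and the strain mean is below the
fresh mean, **produced** if above. No multiple-testing correction is
applied by default; with thousands of features this implies a ~α/2 expected
false-call rate per direction, which inflates per-strain set sizes
accordingly. Benjamini–Hochberg is available (`correction="bh"`) but
changes the calls relative to the raw-p convention. Intensities are tested
untransformed by default (log10 by flag); zero-variance features are
skipped with a warning.

Overlap between strains i and j is asymmetric:
percent[i][j] = 100·|D_i ∩ D_j| / |D_i| with D the depleted sets. Reported
percentages are rounded half-up to one decimal; full precision is kept
internally, and the identity percent[i][j]·|D_i| = percent[j][i]·|D_j|
holds exactly. Phylum-level Euler regions are exact exclusive-subset counts
over the phylum unions of depleted sets; region sizes always sum to the
union size. The altered-feature fraction is
100·|∪(depleted ∪ produced)|/total, reported at two decimals.

## Phylogenetic distances

Newick trees are parsed with dendropy; duplicate leaf labels, unlabeled
leaves and missing or negative branch lengths are rejected. Pairwise
distances are patristic (sum of branch lengths on the leaf-to-leaf path),
in the input tree's branch-length units, and are invariant to re-rooting;
no ultrametric normalisation is applied because downstream use is purely
correlational.

## Co-culture interaction typing

qPCR standard curves (Cq = intercept + slope·log10 copies, slope < 0,
implied efficiency 10^(−1/slope) − 1 constrained to (0, 1.2]) convert Cq to
absolute copies; any per-sample normalisation constant cancels in the
ratio statistic. For strain i paired with partner j, each experiment
contributes

    r_bm = m_i,co(72 h) / m_i,mono(72 h),

the co-culture/monoculture abundance ratio paired by experiment index.
A two-sided one-sample t-test of the (default n = 3) ratios against 1
assigns the sign: + if p < α and the mean ratio exceeds 1, − if below,
0 otherwise. The test is on untransformed ratios by default (the closest
reading of comparing r_bm values across experiments); a log-ratio-vs-0
variant is provided because ratio distributions are right-skewed —
with n = 3 and 20% noise the two rarely disagree, but the log form is the
better-behaved choice for larger effects. Zero-variance replicate sets are
signed by direction with a warning instead of producing an undefined
statistic. An unpaired Welch fallback on raw abundances is available where
experiment pairing is broken.

The unordered sign pair fixes the ecological type: (+,+) mutualism,
(+,0) commensalism, (0,0) neutralism, (0,−) amensalism, (−,−) competition,
(+,−) predation — an exhaustive, symmetric mapping of the nine ordered
pairs onto six types. S strains yield S(S−1)/2 edges (66 for 12), and the
census over types conserves that total.

## Community composition

Endpoint copies are normalised to relative abundances per sample; strains
below the detection limit (default relative abundance 1e-4, an
absolute-copies override exists) keep their computed fraction but carry an
explicit `detected=False` flag rather than an imputed zero. Dropout
comparisons use a two-sided Welch t-test per shared strain on absolute
abundances (fold-change of means, direction label at α). Per-strain scaling
across conditions is a z-score (chosen over min-max so that conditions are
comparable in spread; constant rows scale to zero with a warning). PCA is
performed on the column-centered relative-abundance matrix via
eigendecomposition of its covariance; component signs are fixed by making
each component's largest-magnitude loading positive, explained-variance
fractions are non-increasing and sum to ≤ 1, and components beyond the
matrix rank carry zero variance. No log-ratio transform is applied by
default, matching the convention of ordinating relative abundances
directly; a compositional (clr) variant would change distances and is
deliberately not silently substituted.

## The synthetic twin

The generator exists so that every stage of the pipeline can be tested
against known ground truth at desk scale; its default parameters are the
study conditions, not tuning knobs.

**Growth.** Monocultures follow logistic dynamics dN/dt = μN(1 − N/K),
integrated with fixed-step RK4 and sampled every 10 min over 20 h, inoculum
0.01 OD, additive Gaussian OD noise (default sd 0.005). The default cast
has 12 strains with μ from 0.6 to 1.9 h⁻¹ (four fast, five intermediate,
three slow) and K from 0.4 to 1.0 OD.

**Spent media.** A producer's growth multiplies each of its used features'
"remaining fraction" by (1 − depth) (default depth 0.9). A consumer's
effective capacity in that SM is K scaled by the mean remaining fraction
over its own used features, so full substrate overlap forces
d_AUC ≈ −0.9 < −0.5 and zero overlap leaves d_AUC ≈ 0. Bacteriocin
carry-over multiplies the consumer's rate by exp(−kill·K_producer).

**Metabolomics.** Fresh-medium intensities are log-normal around fixed
per-feature baselines (median 1e5, feature-to-feature sigma 0.8); strain
samples reduce used features by the depletion depth and raise produced
features by the production fold (default 5), with log-normal replicate
noise (default CV 10%). The default resource design allocates 3092 features
in blocks: strain-exclusive blocks plus shared blocks between
phylogenetically close strains (among them a 33-feature block shared by the
370-feature and 128-feature strains, giving the 8.9%/25.8% asymmetric
overlap), so substrate overlap decays with patristic distance on the
packaged 16S-like tree.

**Co-cultures and communities.** Abundances follow generalized
Lotka–Volterra dynamics dN_i/dt = N_i(μ_i + Σ_j a_ij N_j) with bacteriocin
killing folded in as an extra negative coefficient, integrated by
fixed-step RK4 (dt = 0.01 h; growth curves use dt = 1/120 h so the 10-min
sampling grid falls on integration steps) in 24-h batches with
instantaneous 1:100 dilution between batches — 3 cycles (72 h) for pairs,
10 days for communities. Abundances below 1e-12 OD after dilution are set
to zero (extinction floor). Divergence beyond 1e6× capacity aborts with an
error. Observation noise is log-normal on copies (default CV 20%) and
Gaussian on Cq (default sd 0.15 cycles); copies are 2e9 per OD unit.

Interaction strengths are parameterised by the normalized coefficient
c = a_ij·K_j/μ_i, so that at a two-species coexistence point
x_i = 1 + c·x_j in units of K. Defaults: amensal victims at c = −0.8
(settling near 0.2 K, |log2 r_bm| ≈ 2.3), commensal beneficiaries at +3
(≈4 K), predation at +12/−0.1875 (4 K and 0.25 K), competition at −0.9
both ways. The competition value sits at the stable-coexistence limit: a
two-species gLV cannot hold *both* partners below half their capacities at
a stable interior point (that requires interspecific exceeding
intraspecific competition, which destabilises coexistence), so mutual
losers settle near 0.53 K (|log2| ≈ 0.9) and their signs are the
least-powered calls in the network.

The packaged default design encodes a pairwise network of 46 amensal,
7 competitive, 11 neutral, 1 commensal and 1 predatory edges over the 66
pairs, with one bacteriocin producer (five targets, one of them the
predation prey) and a dominance ordering that decides amensal direction.

**What the twin does not emulate.** No explicit resource dynamics
(consumer–resource feedback is collapsed into the spent-media capacity
rule), no pH feedback on growth, no demographic stochasticity, no
higher-order interactions, no qPCR primer cross-reactivity, no MS batch
effects or missing values. Passing tests therefore demonstrate that the
pipeline recovers ground truth under these idealisations, not that the
statistical conventions (raw-p feature calls, ratio-scale t-tests at n = 3)
are optimal for real data. One emergent caveat worth knowing: iterating the
pairwise-calibrated gLV for all 12 strains simultaneously predicts strong
competitive exclusion within 10 passages, more severe than is typical of
real rich-medium communities — pairwise coefficients stack additively in
gLV, which is precisely the regime where higher-order effects matter.

## Problem sizes used in validation

The test-suite and the acceptance script run, per seed: 12 monocultures +
66 pairs over 3 dilution cycles (sign recovery aggregated over 20 seeds at
replicate CV 20%, n = 3); the full 13×12 spent-media curve grid in
triplicate; one 3092-feature table in triplicate; 6000-trial null
calibrations; and a 22-step bisection for the washout threshold
(persistence under daily 1:100 dilution flips at μ = ln(100)/24 ≈ 0.192 h⁻¹,
probed in the low-density exponential regime). These sizes give each check
comfortable statistical resolution while keeping a full run in the
tens-of-seconds range.
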