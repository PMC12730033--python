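# Methods

## Scope and model

`phenodiv` analyses balanced completely-randomized diversity trials of the
kind used to characterize plant germplasm: `g` genotypes (here, spatially
contiguous subpopulations treated as treatments) × `k` replicates × several
quantitative traits, including laboratory seed-quality traits derived from
daily germination counts. The analysis chain is

1. seed/seedling physiology indices per replicate,
2. per-trait one-way ANOVA and genetic-parameter estimation,
3. Scott–Knott grouping of genotype means,
4. genotype divergence (Mahalanobis D², standardized Euclidean),
5. Tocher and UPGMA–Mojena clustering,
6. Singh trait-contribution decomposition and canonical variates,
7. genotype–ideotype distance selection.

The underlying trait model is the additive two-component model
`y_ij = μ + g_i + e_ij`. All estimators are moment-based; normality is
assumed only by the F test's p-values and the synthetic generator.

## Physiology indices

Thousand-seed weight `TSW = 1000·W/N`; germination percentage
`G% = 100·Ng/Nt`; Maguire's speed index `GSI = Σ G_i/N_i` with days counted
from sowing; mean germination time `MGT = Σ(G_i·N_i)/Σ G_i`; biomass density
`DEN = SDM/SL` (mg/cm); vigor index `SVI = G% × SL`. Daily counts are
incremental, with validation `Σ counts ≤ seeds sown`. A replicate with zero
germination has no defined MGT; the cell is emitted as missing and excluded
from that trait's ANOVA with a warning — a 0 or ∞ placeholder would bias
genotype means. The test window defaults to 21 days, configurable.

## Genetic parameters

From the genotype and residual mean squares (QMg, QMr) with `k` replicates:
`Vf = QMg/k`, `Ve = QMr/k`, `Vg = (QMg−QMr)/k` truncated at 0 (the raw value
is kept as a diagnostic), broad-sense repeatability `h² = 100·Vg/Vf` bounded
to [0, 100]. `CVg = 100·√Vg/μ̄`; `CVe = 100·√QMr/μ̄` — the residual SD, not
the SD of a mean. This is the experiment-CV convention of plant-breeding
software and the only one that reproduces the reference trial's printed
CVg/CVe column (e.g. plant height → 0.67, mean germination time → 2.52); it
also makes `CVg/CVe = √Vg/√QMr`, independent of the grand mean. `h²` is a
repeatability of genotype means, not a narrow-sense heritability.

Unbalanced data are rejected by default rather than silently corrected;
`on_missing="drop"` performs the exact unequal-n one-way ANOVA with a
warning and uses the mean replication for `k`.

## Scott–Knott

At each node of the recursion over the descending-sorted means, the
contiguous split maximizing the between-group sum of squares B0 is tested
with `λ = [π/(2(π−2))]·B0/σ̂0²`, `σ̂0² = (Σ(ȳ_i−ȳ)² + df_r·QMr/k)/(g+df_r)`,
against a chi-square with fractional ν = g/(π−2) degrees of freedom
(continuous quantile; rounding ν changes decisions near the threshold).
Ties in B0 break toward the smaller left group. Letters follow the agronomy
convention: 'a' is the highest-mean group.

## Divergence

The D² weight matrix is the pooled within-genotype covariance
(cross-products summed over genotypes, divided by `g(k−1)`; its diagonal is
each trait's QMr) divided by `k`, i.e. the residual covariance of genotype
*means*, so the univariate D² sits on the ANOVA F scale. The raw residual
covariance is available behind a flag. Condition numbers above 1e10 trigger
a pseudo-inverse with a warning. Standardized (and standardized *mean*)
Euclidean distances operate on trait means scaled to mean 0, variance 1
(sample SD, n−1); both variants are exposed because trial reports use
either for the same clustering.

## Clustering

Tocher: inclusion limit θ = max over genotypes of their nearest-neighbour
distance; groups seeded with the closest available pair and grown while the
candidate's mean distance to the group stays ≤ θ (the classic criterion; the
"increase in group mean distance" variant is not implemented as default
behaviour). Ties break by genotype label. UPGMA and cophenetic distances
come from scipy's average-linkage implementation wrapped in a `MergeTree`;
Newick export places each node at depth = fusion height / 2. Mojena's cutoff
is mean + c·SD over all n−1 fusion heights (sample SD), default c = 1.25,
the constant recommended in the stopping-rule literature.

## Trait importance and selection

Singh components `S_j = Σ_{pairs} d_j·(W⁻¹d)_j` sum exactly to the total
pairwise D²; negative components (possible with correlated traits) are
reported signed with a warning, and flooring at 0 is applied only in the
display helper. Canonical variates solve `W⁻¹B` on the standardized-mean
scale via the Cholesky symmetric reduction; signs are fixed by making the
largest-magnitude loading positive. The ideotype defaults to the observed
per-trait optimum in the declared direction (explicit targets supported);
genotypes are ranked by weighted Euclidean distance on the standardized
scale, default weights 1, default selection fraction 30%.

## Synthetic generator

The generator's defaults are the reference study conditions: 20 genotypes ×
4 replicates, 15 traits, 50-seed germination boxes counted daily for 21
days. Per-trait `(mean, σ²g, σ²e)` are calibrated once from the reference
trial's printed mean squares and CV%: `σ²e = QMr`, `σ²g = (QMg−QMr)/k`, and
the grand mean recovered as `100·√QMr/CV%` (e.g. MGT: mean 6.0 d, σ²g 0.57,
σ²e 0.09). Genotype and residual effects are normal; germination
probability varies between genotypes on the logit scale (SD 0.5 around
0.95) and germination timing is a truncated normal on [0.5, n_days+0.5]
(seed-to-seed SD 1.5 d, genotype SD 0.75 d around day 6) rounded half-up,
so day 0 cannot occur and non-germinating seeds are censored. One RNG
stream per call, explicitly seeded: fixed seed ⇒ bit-identical output.

What it does not emulate: spatial structure, genotype×environment
interaction, dormancy, non-normal or heteroscedastic residuals, and
between-trait residual correlation (traits are drawn independently, so the
pooled covariance is near-diagonal). Passing tests therefore demonstrate
correctness of the estimators and algorithms under the stated model, not
robustness to those features of real data.

## Numerical choices and problem sizes

Chi-square and F quantiles from scipy; no global state anywhere;
tie-breaking is lexicographic throughout so reruns are byte-identical. The
Monte-Carlo checks use 20×4 trials — 500 replicates for repeatability
recovery (truth 0.80 and 0) and 300 inside the acceptance script — sizes at
which the estimator's small-sample truncation bias (mean ĥ² ≈ 0.77 at truth
0.80) is visible but within the ±0.05 band the recovery tests assert.

## Known limitations

Only balanced (or explicitly complete-case-reduced) one-way layouts; no
REML/mixed models or multi-environment analysis; D² is not a metric and no
triangle inequality is claimed for it; Scott–Knott is the original
chi-square approximation, not bootstrap variants; Mojena's constant is a
convention — with unreleased field data neither the published cutoff value
nor published group memberships can be reproduced, only the method and the
shapes of its outputs.
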