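# Methods

## The interaction model

Each feature (gene or miRNA) is modelled independently by ordinary least
squares on log2 intensities with eight 0/1-coded terms: an intercept,
tumor tissue (`CeT`), three dose indicators (`doL`, `doM`, `doH`), and
their products. Because the design is saturated in the eight
tissue×dose cells, every coefficient is a cell-mean contrast; in
particular `CeT:doH` equals the difference-in-differences
`(T_H − P_H) − (T_sham − P_sham)` exactly (this identity is an oracle
test). Samples are treated as independent — paired tumor/parenchyma
samples from the same animal are *not* modelled with a random effect,
which reproduces the published analysis assumption and is also how the
synthetic generator draws data, so model and generator are consistent.

Inference is the classical t test with `df = n − 8` and the pooled
per-feature residual variance; no empirical-Bayes moderation is applied
(the model is stated as plain OLS; a moderated variant would change the
q-value ordering for low-variance features). Multiplicity is controlled
per term across features with Benjamini–Hochberg step-up q-values
(gene analysis at FDR 0.01, miRNA analysis at FDR 0.05). Contrasts
`w·β̂` use the unscaled covariance `(X'X)⁻¹` with the same residual
variance and df.

Four named contrasts drive the miRNA subset tree:

| contrast | weights | meaning |
|---|---|---|
| `ms_in_parenchyma` | `doH` | smoke effect in parenchyma, H vs sham |
| `ms_in_tumor` | `doH + CeT:doH` | smoke effect in tumors |
| `tissue_in_sham` | `CeT` | tumor-vs-parenchyma difference, sham |
| `tissue_in_ms` | `CeT + CeT:doH` | tumor-vs-parenchyma difference, exposed |

## miRNA subset classification

Only features with interaction q < 0.05 are classified. Level 1 tests
the two smoke contrasts at raw p < 0.05 (raw, not FDR-adjusted — the
published rule): significant in parenchyma only, in tumors only, in
both (subdivided by the signs of the two effects into discordant /
concordant), or in neither (`unclassified`). Level 2 splits the
parenchyma-only group by the tissue contrasts: no sham tissue
difference (`exposure-only`), a sham difference that disappears under
smoke (`tissue-effect-vanishes`), or a difference in both conditions.
Level 3 splits the last group by the sign pattern of the two tissue
contrasts: `tumor-high` (+,+), `tumor-low` (−,−), `mixed` otherwise.
The `mixed` rule is a documented operationalization of the verbally
described small subgroup (features whose parenchyma level rises while
the tumor level is stable); no formal rule was published for it.

A consequence worth stating plainly: every truly-zero contrast crosses
raw p < 0.05 with probability 0.05 regardless of effect sizes or noise
level. With ~65 features whose second smoke contrast is exactly zero,
about three per run leak from the single-tissue categories into
`both`, and BH admits ~2–3 null features among the discoveries. Planted
category counts are therefore recovered with a systematic offset of a
few features — this is a property of the published decision rule, not
of the implementation, and it is why the recovery tests carry small
tolerances rather than exact equalities.

## Signature extraction

The extractor repeats R = 50 times: a class-stratified random split
placing `ceil(0.2·n_class)` samples in training; SAM ranking
`d = (mean₁ − mean₂)/(s + s0)` on the training samples only (avoiding
selection bias in the test error); selection of the top-N genes by
|d|; a linear-kernel SVM (C = 1); and the test-set misclassification
fraction `P(N, iter)`. `Per(N)` is the mean of the recorded errors and
the consensus signature is the N genes most frequently selected, ties
broken by mean |d| across iterations and then by gene id — fully
deterministic given the master seed, which spawns one child stream per
iteration. The fudge constant s0 defaults to the 90th percentile of the
per-gene pooled standard errors; the published description names SAM
without its tuning recipe, and a fixed quantile keeps the statistic
deterministic. `s0 = 0` recovers the pooled t statistic (tested).
With a 20% training fraction the training set can be as small as four
samples; this is implemented as stated, and iterations whose training
split degenerates are recorded and flagged rather than silently
dropped.

## Synthetic data

The generator states a world matching the study's printed structure:
the gene-expression design (parenchyma 2/2/5/5, tumor 8/8/6/9; 45
arrays) and the miRNA design (parenchyma 10×4, tumor 8/7/6/9; 70
arrays). Per feature, the expectation is `baseline + x'β` through the
same design the model fits; baselines are uniform on 6–12 log2 units
(typical microarray span), residuals i.i.d. Gaussian with SD 0.25
log2 units. The published work states neither noise magnitudes nor
effect sizes; SD 0.25 and unit (1.0 log2) planted effects — i.e. 4
residual SD — are this package's fixed choices of a realistically
strong signal, chosen once.

Planted classes map each terminal category of the subset tree to a unit
coefficient pattern whose nonzero contrasts all have magnitude ≥ 1 (so
every decision in the tree is powered) and whose "non-significant"
contrasts are exactly zero (so leakage is minimal and quantifiable).
The eight categories are planted at the published subgroup sizes
3/35/2/5/17/3/4/1 by default.

miRNA probe-level output adds: four replicate spots per feature
(independent re-noised draws of the feature's expected value — with no
animal random effect, technical replicates are distributionally
identical to biological samples, matching the independence assumption);
planted always-absent features written at one constant raw intensity,
so the per-array 5th-percentile threshold ties with them and the
documented "ties are absent" rule removes exactly those features; and
extra outlier arrays created by permuting a copied array's values
within the array, which destroys between-array correlation at any
scale. Defaults (289 features, 10% absent, one outlier) reproduce the
published 260 × 70 post-filter geometry end to end.

What a green recovery test does **not** establish: the generator has no
probe affinity structure, no spatial artifacts, no dye chemistry, no
animal-level correlation, and baselines are exchangeable across
features. Two consequences are documented rather than patched:
(1) with heterogeneous baselines and no planted-absent block, the
features with the lowest baselines sit below the 5th-percentile
threshold in every array and are legitimately filtered — dim features
on real arrays behave the same way; (2) quantile normalization of this
baseline-dominated world maps near-deterministic ranks onto the common
quantile vector and thereby deflates residual variance, so p-values
computed downstream of quantile normalization on synthetic data are
anti-conservative. Planted-truth inference is therefore scored on
summary-level simulations, and the preprocessing chain is validated on
its own contracts (shape, filtering, QC, oracle equivalences).

## Numerical choices

- **normexp**: per-array method-of-moments estimation of the
  normal-background + exponential-signal convolution
  (`α̂ = (m₃/2)^{1/3}`, `σ̂² = var − α̂²`, `μ̂ = mean − α̂`), with a
  pure-signal fallback for degenerate (symmetric or constant) arrays;
  the corrected value is the closed-form conditional expectation
  `E[S|X=x]` (verified against numerical integration) plus the offset
  (default 10).
- **Quantile normalization**: average ranks, interpolated into the
  across-array mean quantile vector; single-column input returned
  unchanged.
- **Median polish**: alternating row/column median sweeps until the
  total absolute residual stabilizes (relative tolerance 1e-10, cap
  100 iterations); the feature summary is overall + column effects.
  Verified against an independent naive implementation and against R's
  `stats::medpolish`.
- **Detection calls**: linear-interpolation empirical quantile;
  present iff strictly above the threshold, so ties are absent.
- **Outlier screen**: mean Spearman correlation with the other arrays,
  flagged below `median − 3·IQR`; the published rule names no cutoff,
  so k = 3 is configurable.
- **Group filter**: "four sample groups" is read as the four dose
  groups pooled across tissues (`group_by="dose"`); the eight-cell
  reading is available as `group_by="cell"`.
- **Clustering**: scipy complete-linkage agglomeration; Euclidean and
  squared-Euclidean give identical topologies (monotone transform), and
  determinism follows from scipy's fixed merge order.
- **Degenerate inputs**: rank-deficient designs raise with the empty
  cells named; zero contrasts are rejected; constant features get
  t = 0 rather than NaN.

## Known limitations

- No empirical-Bayes variance moderation and no animal-level random
  effects (both deliberate, matching the published analysis).
- The signature extractor offers only the linear SVM; the classifier
  contract is pluggable but alternatives are out of scope.
- The raw-p classification rule's 5% leakage per zero contrast bounds
  how exactly category counts can ever be recovered; see above.
- Heatmaps are plain matplotlib renderings of the leaf-ordered matrix,
  not replicas of the published figures.
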