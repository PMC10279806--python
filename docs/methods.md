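# Methods

## Pipeline overview

`multinet` turns per-modality subject × feature tables into a multiplex
subject-similarity network and partitions it by multilayer modularity
maximization. The stages run in a fixed order; every stage is deterministic
given the `RunConfig` seed.

1. **Complete-case alignment.** All modality tables, the covariate table
   and the label table are restricted to the subjects present in every
   input, keeping the first table's row order. Dropped subjects are logged
   together with the input that excluded them; nothing is removed silently.

2. **Preprocessing** (per modality, in this order):
   * *mean centering* of each feature;
   * *covariate residualization*: ordinary least squares of each feature on
     an intercept plus the modality's covariate set, keeping the residual.
     Defaults: age + sex + total intracranial volume for structural volumes
     and amyloid-PET SUVRs; age + sex for CSF analytes and cognitive
     scores; sex only for genetics. Covariates enter on their raw scale; a
     rank-deficient design is an error naming the collinear columns.
   * *normalization*: min–max to [0, 1] per feature, except genetics which
     is z-scored (sample SD, ddof 1). "Divide by the column maximum" is
     available as `max_divide` for users wanting that literal convention,
     but it cannot map residualized (signed) data into [0, 1], so min–max
     is the default reading of "scale between 0 and 1". Constant columns
     become 0.5 / 0 with a warning rather than an error.
   The output table carries a `preprocessed` flag; running the composition
   twice is rejected because min–max scaling is not idempotent.

3. **Similarity layers.** Within each modality, the edge weight between two
   subjects is the Pearson correlation of their preprocessed feature
   vectors (Spearman available). The diagonal is zero; weights stay signed
   by default (`keep_signed`), with `clip_negative` and `shift_rescale`
   offered for users who need classical nonnegative graphs. Correlations
   over very few features are unstable — with 3 features the attainable
   values are nearly ±1 — so the builder refuses < 2 features and warns
   below 3.

4. **Multilayer assembly.** Layers are stacked with *categorical* coupling:
   each subject's copy in layer *l* is linked to its copies in every other
   layer with uniform weight ω (modalities carry no natural order; an
   ordinal chain is available in the config). The per-layer null model is
   the configuration model. For signed layers the positive and negative
   parts are nulled separately,

       M = k⁺k⁺ᵀ / 2m⁺ − k⁻k⁻ᵀ / 2m⁻,

   which equals the Newman–Girvan null `k kᵀ / 2m` whenever the layer is
   nonnegative and preserves the row-sum identity Σⱼ M_ij = k_i. The plain
   Newman–Girvan form divides by the *signed* total weight, which for a
   near-balanced signed layer (e.g. a 3-feature correlation layer) is close
   to zero and produces unbounded null entries; the split form stays
   bounded. `newman_girvan_null` remains available and selectable
   (`null_model="newman_girvan"`). The normalizing total weight 2μ
   accumulates Σ|A| per layer plus every interlayer coupling counted from
   both endpoints; using absolute intra-layer strength keeps 2μ positive
   for signed layers and is a pure scale factor on Q.

5. **Community detection** maximizes

   Q = (1/2μ) Σ_{ijlr} [ (A_ijl − γ_l M_ijl) δ_lr + δ_ij ω_jlr ] δ(g_il, g_jr)

   with an iterated generalized Louvain on the dense supra-modularity
   matrix B (diagonal blocks A_l − γ_l M_l including the null's diagonal,
   off-diagonal blocks ω·I):
   * *phase 1*: visit node-layers in a seeded random order; move each to
     the community with maximal positive gain (computed directly on B, so
     signed entries need no special casing), repeating until a full pass
     makes no move. Ties keep the current community, otherwise the lowest
     community id wins. A node net-repelled by every community (possible
     only with signed weights) is isolated into a fresh community — without
     this move the sweep can converge strictly below single-move
     optimality.
   * *aggregation*: communities become super-nodes (B is summed over
     blocks, diagonal blocks becoming self-loops) and phase 1 repeats,
     until no level improves.
   * *iteration*: the converged partition re-seeds a fresh run at the base
     level until Q improves by less than `tol` (default 1e-10).
   * *restarts*: restart 0 starts from all-singletons; later restarts start
     from a random initial partition. Maximal-gain trajectories from the
     singleton start are nearly insensitive to visit order, so random
     initial partitions are what actually diversifies the search on
     frustrated signed instances; the best-Q partition over restarts
     (default 20) is returned. Exhaustive enumeration over all set
     partitions of ≤ 8 node-layers confirms the optimizer reaches the
     global optimum across hundreds of random signed instances.

   Defaults γ_l = 1 for every layer and ω = 1, both exposed in `RunConfig`.
   The number of communities is emergent from Q, never fixed in advance.

6. **Consensus and evaluation.** Each subject's consensus label is its
   majority community across layers (ties go to the earliest layer; a flag
   records split subjects). Communities are cross-tabulated against
   diagnosis — baseline (early/late MCI collapsed to MCI) or final, where
   subjects lost to follow-up are dropped and counted. The community with
   the largest share of AD subjects is AD-dominant, the largest CN share
   CN-dominant, others intermediate. Sensitivity is the percentage of AD
   subjects in the AD-dominant community, specificity the percentage of CN
   subjects in the CN-dominant community; MCI enters neither, and with more
   than two communities intermediate ones count as misses. Confidence
   intervals are exact Clopper–Pearson (beta quantiles; this is the method
   that reproduces reference bounds to their reported precision, which Wilson
   does not). Amyloid stratification marks SUVR ≥ cutoff (default 1.11) as
   positive — the boundary value is positive by decision, configurable.
   Longitudinal transitions (stable CN/MCI/AD, CN→MCI, CN→AD, MCI→AD
   converters, MCI→CN reverters) are counted per community with
   within-category percentages. Per-feature group contrasts use the
   two-sided Mann–Whitney U with the `min(U_a, U_b)` convention, scaled by
   the maximum U across the features tested, with Bonferroni (family =
   features in the call) or Benjamini–Hochberg control at 0.05.

## Synthetic cohort generator

The generator plants a latent subtype z_i (uniform over K, default 2) and
emulates the structure the analysis assumes: a community signal shared
across modalities, expressed in each layer only with probability ρ
(per subject × layer), plus modality-specific noise and covariate
confounds.

* **Features.** Per modality, a fraction (default 0.5) of features is
  "affected": subjects whose subtype expresses in that layer receive a mean
  shift of Δ (default 1.0) noise-SD units per unit of subtype code. All
  other variation is iid Gaussian noise plus linear age/sex (and ICV for
  imaging layers) effects — the same covariates the preprocessing
  residualizes, so the confounds are realistic but removable. Genetics is
  discrete-ish: a risk-allele count 0–2 with subtype-dependent frequency
  (0.15 → 0.40) plus two continuous polygenic-style scores.
* **Labels.** Baseline diagnosis is drawn from subtype-specific CN/MCI/AD
  mixtures (healthy-like 60/40/0, AD-like 0/65/35, chosen to echo a
  memory-clinic cohort's composition); with probability ε (default 0.1) a
  subject draws from the *other* subtype's mixture, and these flips are
  recorded in the truth table. MCI splits into early/late by a severity
  median. Final diagnosis follows the true subtype: AD-like subjects
  convert to AD with the configured probability (default 0.4), healthy-like
  MCI reverts to CN with default probability 0.3. Amyloid SUVR is drawn
  per subtype around the 1.11 positivity boundary (healthy-like
  N(1.02, 0.06), AD-like N(1.30, 0.15)); follow-up time is N(4.5, 2.5)
  years, clipped positive.
* **What it does not emulate:** spatial covariance between brain regions,
  within-modality feature correlation, site effects, linkage structure, or
  missingness mechanisms beyond optional loss to follow-up. Passing tests
  on this generator therefore show the pipeline recovers a planted
  cross-modality partition under iid noise — not that it handles the full
  covariance structure of real imaging or biomarker panels.

`recovery_score` is the adjusted Rand index between the consensus partition
and the planted subtypes (chance-corrected; 1 = identical up to
relabeling).

## Numerical choices

* Move acceptance uses an absolute slack of 1e-12 × max|B| so floating-
  point ties cannot cycle; Q convergence tolerance defaults to 1e-10.
* Community ids are compacted to 0..K−1 by first appearance, making
  partitions reproducible byte-for-byte across runs with the same seed.
* All randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawning; there is no global random state.
* CSVs are written with 12 significant digits, which round-trips the
  pipeline's quantities exactly at double precision for the tested
  tolerances.
* Degenerate inputs: constant feature columns warn and map to neutral
  values; a subject with a constant feature *row* is an error naming the
  subject (its correlation is undefined); a layer with zero total weight is
  an error.

## Problem sizes and validation

The test suite and the acceptance script validate on: exact closed-form
instances (triangles, stars, planted blocks, two disconnected 3-cliques
where the optimal single-layer partition scores Q = 0.5); brute-force
quadruple-sum modularity oracles on random signed instances (n ≤ 6, L ≤ 3);
exhaustive set-partition enumeration for global optimality on ≤ 8
node-layers; and synthetic cohorts of 30–200 subjects with the default
five-modality feature counts (90/68/3/6/3). Reference contingency counts
for a 484-subject two-community solution are used as fixed inputs to verify
the evaluation arithmetic (91.1% / 82% and their exact CI bounds).

## Known limitations

* With the default γ = 1 and signed correlation layers, modalities with
  very few features (3-analyte CSF, 3-feature genetics) produce near-±1
  correlations whose block structure carries large modularity mass while
  containing little subtype information; such layers can dilute recovery
  rather than aid it. Per-layer γ_l (exposed in the config) is the natural
  counterweight, but no automatic calibration is provided.
* Louvain-type optimization is greedy; global optimality is verified only
  at small problem sizes, and large instances inherit the usual local-
  optimum caveats despite random-restart diversification.
* Sensitivity/specificity reduce a K-community solution to two labeled
  communities; intermediate communities are treated as misses by design.
* The generator's iid feature noise makes between-subject correlations
  concentrate more tightly than in real data with correlated features;
  effect sizes calibrated on it do not transfer directly to real cohorts.
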