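# Methods

## Scope and data model

`teanet` operates on a sample × feature table of strictly positive relative
intensities from an untargeted LC–MS run (`AbundanceMatrix`), optionally
joined with a sample × gene FPKM-like table (`ExpressionMatrix`). Upstream
steps — acquisition, peak detection, compound identification, read alignment
and FPKM computation — are out of scope; the package starts at the
quantified table. Missing intensities are kept as missing and handled by
pairwise-complete deletion in correlations; they are never imputed or
zero-filled. All analyses of intensity treat the data as multiplicative and
work on the log10 scale (QC correlation, test statistics, PCA, network
correlations); fold changes are formed on the raw scale.

## QC stability

Pooled-QC injections are replicate measurements of one extract, so their
profiles should agree up to instrument drift. The screen computes Pearson
correlation between every pair of QC rows on log10 intensities and passes
when the minimum pairwise PCC meets the threshold (default 0.99, the
conventional lower edge of a stable run's 0.99–1 band). Log scale is a
deliberate choice — drift in electrospray response is multiplicative — and
the report is invariant to global intensity rescaling and to QC ordering.
No drift correction or batch normalization is attempted.

## Variability

Per feature, variability is the fold range `V = max/min` over biological
samples (QC excluded), defined for strictly positive values and ≥ 1.
Tier labels: `<3` for V < 3, `3-5` for 3 ≤ V < 5, `5-1000` for
5 ≤ V ≤ 1000, `>1000` for V > 1000, with an additional flag above
3000-fold. The boundaries 3 and 5 belong to the upper tier; 1000 stays in
`5-1000` because `>1000` is strict. V is scale-invariant but *not* robust:
it is driven entirely by the two extreme samples, which is exactly what
makes it useful for flagging genotype-restricted secondary metabolites.

## PCA and grouping

PCA is computed on log10, autoscaled (unit-variance) intensities of the
biological samples via SVD; a center-only mode exists for sensitivity
checks. Constant features are dropped (with a warning) under autoscaling.
QC samples are passively projected into the fitted space — in a stable run
they sit at the centre of the score plot. Explained-variance percentages
are non-increasing and sum to 100 when all `min(n−1, p)` components are
kept.

Group assignment is k-means (default k = 3, 25 restarts, fixed seed) on the
first two score columns; clusters are renumbered by descending size with
lexicographic tie-breaks so labels are deterministic. The package makes no
claim that k-means reproduces any particular published grouping — group
boundaries drawn on a score plot by eye are not an algorithm — it provides
a reproducible, seeded stand-in, and labels can be supplied manually
through the sample metadata instead.

## Differential accumulation

For a group pair (A, B): `log2FC = log2(mean_A/mean_B)` on raw intensities
(geometric-mean mode available), two-sided p from Welch's t-test on log10
intensities (Wilcoxon rank-sum selectable), Benjamini–Hochberg FDR across
all features, and the two-gate call `|log2FC| > log2(2)` and `q < 0.05`,
both strict. Welch on logs was chosen over count-model packages because
LC–MS relative intensities are continuous, positive and approximately
lognormal — a negative-binomial count model is misspecified for them — and
the two-gate decision rule is preserved regardless of the test. Features
with identical constant values in both groups have an undefined t statistic
and are assigned p = 1 (no evidence). The fold-change and significance
gates are antisymmetric under pair swap.

## Mutual-rank networks

For a node set (metabolites, or pathway genes plus metabolites):

1. all-pairs Pearson r on log10 values (expression enters as
   log10(FPKM + 1) since FPKM may be exactly 0), pairwise-complete; pairs
   with fewer than 4 complete observations are flagged untestable and
   excluded from inference;
2. p from the t transform `t = r·sqrt((n−2)/(1−r²))` with n−2 df,
   two-sided, p = 0 at |r| = 1; BH q over all testable pairs in the batch
   (the batch is the set of pairs entering that network — FDR scope is
   otherwise arbitrary);
3. each node ranks its partners by **signed** r from high to low (a strong
   negative correlation ranks last); ties receive the average rank;
4. `MR = sqrt(rank_ab · rank_ba)` by default. The raw product
   `rank_ab · rank_ba` is selectable; the geometric mean is the default
   because the decay constant of 100 in the weight function is calibrated
   for geometric-mean MR in the co-expression network literature, and a raw
   product would compress all weights toward the floor;
5. weight `w = exp(−(MR−1)/100)`, mapping MR ∈ [1, ∞) to (0, 1], with
   `w ≥ 0.01 ⇔ MR ≤ 1 + 100·ln 100 ≈ 461.52`;
6. an edge is kept when `q < 0.05`, `|r|` strictly exceeds the PCC gate
   (0.8 for metabolite-only networks, 0.4 when genes are involved — gating
   uses the absolute value even though ranking is signed) and
   `w ≥ 0.01` (the floor is inclusive, matching the "≥ 0.01" convention).

The gene–metabolite network is built on the merged node set (user-supplied
pathway genes + all metabolites): ranks and FDR are computed jointly and
all resulting edge types are kept, so an empty gene list reduces exactly to
the metabolite network. Hubs are degree rankings (ties lexicographic),
restrictable to one node kind; components are maximal connected components,
largest first, with isolated nodes retained so sizes partition the node
set. Networks export as edge-list TSV, SIF and GraphML in lexicographic
order (byte-stable).

## Synthetic cohorts

The generator emulates the target study design and nothing finer: it starts
at the quantified feature table (no m/z, retention time, adducts or
peak-detection noise). Defaults: 68 accessions, 250 features with aa/bb/cc
ids mirroring standard/literature/database identification tiers, 60 genes,
3 equal-sized groups, 7 pooled-QC injections at 1% CV (one QC per ~10
injections).

Log10 intensity of feature f in sample s:

```
x_sf = mu_f + delta_{g(s),f} + dam shifts + s_f · (sqrt(r_m)·z_m,s + sqrt(1−r_m)·e_sf)
```

* `mu_f ~ N(5, 1)`: base log10 levels spanning a few decades.
* `s_f`: per-feature spread from two regimes — narrow U(0.02, 0.09)
  ("primary-like", 15% of features) and wide U(0.2, 0.9)
  ("secondary-like") — so the max/min statistic at n = 68 spans <3-fold to
  ≫1000-fold, matching the qualitative contrast between conserved primary
  and genotype-driven secondary metabolites. A scalar override
  (`feature_log_sd`) exists for calibration studies that need one known CV.
* `delta`: group shifts drawn with sd `0.5·s_f`. Scaling the shift by the
  feature's own spread keeps the intra-class correlation per feature at
  0.2 for every feature; a fixed absolute shift would make narrow features
  group-dominated and create spurious high correlations between unrelated
  features. With 3 groups this plants a rank-2 structure that PCA's first
  plane captures, with centroid separation ≈ 6–7× the within-group spread
  on PC1/PC2. Module members and dam-spec features are exempt from these
  random shifts so planted correlations and effect sizes are exact.
* modules: members share a latent factor, column = `sqrt(r)·z +
  sqrt(1−r)·eps`, giving expected pairwise correlation exactly `r`. The
  default design plants a tight 7-member block at r = 0.9 (a
  procyanidin/caffeine-like cluster) and a broad 25-member block at
  r = 0.4.
* dam specs: ±`log2_effect/2` in log2 applied to the two groups, so the
  group geometric-mean ratio is exactly `2^effect` in expectation.
* QC rows: the grand-mean biological profile times lognormal noise with
  sigma = `sqrt(ln(1+CV²))` (exact coefficient of variation; CV = 0 gives
  identical rows).
* hub genes: the gene's log profile is `c·m + sqrt(1−c²)·eta`, where m is
  the standardized mean of the standardized target profiles and c is
  calibrated against the realized correlation between m and the targets so
  the gene–target PCC lands at the requested r (0.6 by default against the
  25-member block). A hub cannot exceed the correlation ceiling set by its
  targets' mutual correlation — tracking k mutually independent profiles
  caps the achievable r at ~1/sqrt(k) — which is why the default hub
  targets a correlated block.
* expression: lognormal around log10 FPKM ≈ 2 with sd 0.8.

Determinism: one global seed feeds a named substream per sub-generator
(CRC-derived `SeedSequence` children), so identical seeds give
byte-identical tables and enlarging one component does not perturb others.

What the generator does **not** emulate: missingness mechanisms, intensity
drift within a batch, heteroscedastic technical noise, correlated gene
backgrounds, non-lognormal heavy tails. Passing recovery studies therefore
demonstrate correctness of the analysis chain under the stated generative
model, not performance guarantees on any real panel.

## Validation studies and problem sizes

`teanet.validation` (exercised by the test suite and by
`scripts/acceptance.py`) runs each stage against planted truth:

* **Module recovery** — 50 cohorts, 68 samples × 100 features, one
  7-feature module at r = 0.9; median within-module edge recall and pooled
  between-module false-edge rate through the default gates. Observed:
  recall 1.0, false-edge rate 0.
* **DAM calibration/power** — 200 two-group cohorts (20/group, 250
  features, 10% within-group CV): global-null mean fraction of q < 0.05
  calls (observed ~2·10⁻⁴, bound 0.05) and detection rate of one planted
  4-fold feature (observed 1.0, bound 0.99).
* **QC band** — 200 cohorts at 1% QC CV: fraction with min pairwise
  PCC ≥ 0.99 (observed 1.0; typical min PCC ≈ 0.99998).
* **Hub recovery** — 100 default cohorts: how often the planted hub gene
  tops the gene degree ranking of the gene–metabolite network (observed
  1.0).
* **Group recovery** — 100 cohorts, 100 features: median adjusted Rand
  index of k-means groups vs planted labels (observed 1.0) at a median
  PC1/PC2 centroid-separation-to-within-spread ratio ≈ 6.4.

These study sizes give stable rates in tens of seconds on a single core and
were fixed as the package's standard evidence. The simulated cohort is not
calibrated to reproduce any particular published dataset's numbers (e.g.
its PC1 share of variance is ~7%, not tens of percent): dataset-dependent
quantities require the original matrices.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1] before the t transform; |r| = 1 maps
  to p = 0.
* Zero-variance columns are excluded from correlation and PCA with a
  warning rather than an error.
* Ranking ties get average ranks; remaining ordering ambiguity (hub lists,
  edge output, components) is broken lexicographically by node id.
* BH is statsmodels' `fdr_bh` in `differential` and an equivalent local
  step-up inside the correlation batch; both are property-tested against a
  brute-force step-up implementation.
* Serialized numbers use `%.12g`, making write→read round trips lossless at
  12 significant digits and outputs byte-stable across runs.
* Strict vs inclusive gates: PCC and FDR gates and the fold-change gate are
  strict; the decay weight floor is inclusive.

## Known limitations

* The network is co-occurrence, not regulation: no partial correlations,
  no Gaussian graphical model, no causal claims.
* Pathway gene selection is a user-supplied id list; sequence-based pathway
  annotation is out of scope.
* k-means grouping assumes roughly isotropic clusters on the PC plane; real
  germplasm structure can be gradient-like, in which case group labels are
  a discretization convenience.
* The variability statistic is extreme-value based and sensitive to single
  outlier samples; it is reported alongside max and min so outliers can be
  traced.
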