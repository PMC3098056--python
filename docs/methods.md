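# Methods

## Problem setting

`peakbn` operates on processed TOF-MS peak tables: a matrix of peak
intensities (cases × features), each feature an aligned peak identified by
its m/z value, each case a spectrum labelled with a binary clinical class
(e.g. disease / normal). Sample sets in profiling studies are small
(hundreds of cases) relative to the number of peaks, so conventional
wrapper-style feature selection overfits badly: selected feature sets churn
from run to run and cross-validated error rates fail to predict performance
on withheld data. The package implements a model-free alternative: screen
features by mutual information with the class against a permutation-derived
significance threshold, organise the survivors into a class-rooted Bayesian
network, and judge every arc by how often it recurs under repeated
cross-validation.

## Information measures

All quantities are empirical (maximum-likelihood) estimates on discrete
data, in bits:

- MI(X;Y) = Σ_{x,y} P(x,y) log₂ [ P(x,y) / (P(x)P(y)) ], with 0·log 0 := 0.
- CMI(C;V₂|V₁) = Σ_v P(V₁=v) · MI(C;V₂ | V₁=v), computed by partitioning
  the sample on V₁; strata with fewer than two cases contribute nothing.

No shrinkage or entropy-bias correction is applied anywhere in the
screening path; the only smoothing in the package is the Laplace
pseudocount inside the classifier's CPTs. This keeps the screening
statistic exactly comparable between the observed data and its permutation
null.

## Three-bin max-MI discretization

Each feature is discretized into low / medium / high by choosing the two
cut points (b_low < b_high) that maximize MI(class; binned feature). The
point of three bins rather than two is to isolate the central, weakly
informative part of a marker's distribution: for a diagnostic peak the low
and high bins each become strongly class-pure while the middle bin absorbs
the overlap region.

Search strategy:

- **Exhaustive** (the reference): every midpoint between consecutive
  distinct values is a candidate cut; all ordered pairs are scored. Used
  whenever the feature has at most `exhaustive_cap` (default 64) candidate
  cuts.
- **Quantile**: above the cap, 64 candidate cuts are placed at evenly
  spaced sample quantiles (snapped to actual value midpoints), all pairs
  scored, and the winner is then polished by coordinate-wise refinement —
  holding one cut fixed, the other is re-optimized over *all* distinct-value
  midpoints, alternating until stable (at most 10 rounds). The refinement
  makes the quantile mode agree with the exhaustive optimum to well within
  0.01 bits in testing; without it, gaps slightly above 0.01 bits occur.

Conventions: a value exactly equal to a boundary falls in the medium bin
(the extreme bins stay strictly extreme); ties between boundary pairs are
broken deterministically by grid order; features with two distinct values
fall back to a single cut, constant features to an all-medium bin with
MI = 0, and both fallbacks are flagged. New data binned with frozen
boundaries may fall outside the training range; such values simply land in
the low or high bin and are never rejected.

## Permutation significance threshold

The null distribution of the *maximized* MI is far from the unoptimized
null, so the baseline must absorb the optimizer: class labels are permuted
`n_perm` (default 100) times and every feature is **re-discretized from
scratch** against each permuted labelling. The largest MI over all features
and permutations is the baseline, and the working threshold is
`multiplier × baseline` with multiplier 3.2. The multiplier is an empirical
safety factor; the package exposes it as a parameter and ships a `sweep`
subcommand that reports first-level set size and CV error across a
multiplier grid, because the stability/error trade-off is data-dependent.
Permutations are drawn sequentially from one seeded generator, so the
baseline is non-decreasing in `n_perm` at fixed seed.

The baseline is computed once from the full training table before
cross-validation begins, not per fold (a flag recomputes it per fold).
This is a deliberate trade: the threshold is a global property of the
data's dimensions and noise level, recomputing it 1000 times is expensive,
and holding it fixed makes fold-to-fold feature selection differences
attributable to the folds themselves. The *discretization boundaries*, by
contrast, are always re-learned inside each training fold — held-out cases
never influence them (this is asserted by a poisoning test).

## Network construction

1. **First level.** Every feature whose MI(class; binned feature) strictly
   exceeds the threshold gets an arc from the class node.
2. **Linking.** Each first-level feature is tested against every other
   feature on the already-binned values. Because a pair of 3-level features
   can reach log₂ 3 bits while MI with a binary class is capped at 1 bit,
   the comparison is scale-adjusted: pair MI divided by log₂ of the smaller
   alphabet of the pair, against threshold divided by log₂(#classes).
   First-level → non-first-level links are directed immediately (the class
   is assumed causal, so dependence flows downward).
3. **Orientation / demotion.** For a linked pair of first-level features,
   both conditional values CMI(C;V₂|V₁) and CMI(C;V₁|V₂) are computed
   (V₁ = the larger class MI). A fractional drop
   1 − CMI(C;V₂|V₁)/MI(C;V₂) strictly greater than `drop_threshold`
   (default 0.75) means V₂'s class dependence is explained by V₁: the
   class→V₂ arc is removed and V₁→V₂ added (serial chain). If both
   directions drop, the larger drop decides; a drop of exactly the
   threshold does not demote. If neither drops, both stay first-level and
   the arc runs from the feature with the greater retained conditional MI.
   Pairs are processed in descending order of the stronger member's class
   MI; a pair whose member was already demoted is skipped (each demoted
   feature keeps a single parent), and any orientation that would close a
   cycle is skipped and logged, which guarantees a DAG with the class as
   sole root. Second-level children attach to their single strongest
   first-level parent by pair MI; children of children are not searched.
   Every decision is recorded in an auditable log (rule, MI before/after,
   drop fraction).
4. **Consensus.** After repeated CV, an undirected connection appearing in
   strictly more than `freq_threshold` (default 0.5) of the n·k networks is
   kept, with the majority direction; arcs are added in descending
   frequency order under the same cycle guard.

## Classifier

Only the first-level features — the Markov blanket of the class node —
enter the classifier: P(class | bins) ∝ P(class) · Π_f P(bin_f | class).
CPTs are empirical counts with Laplace pseudocount 1 (exposed as a
parameter), class priors are empirical frequencies, and the product is
accumulated in log space so thousands of features cannot underflow. Binary
calls use a 0.5 posterior threshold with a strict inequality: a posterior
of exactly 0.5 is a negative call. ROC curves sweep the posterior of the
designated positive class. A fitted classifier serializes to JSON
(boundaries, priors, CPTs, threshold) so it can be frozen, shipped, and
applied to later data without refitting anything.

## Cross-validation protocol

Stratified 10-fold CV repeated 100 times (defaults), fold membership
reshuffled every repeat; per repeat every case is tested exactly once and
one error rate is recorded; all n·k per-fold networks are tallied by arc.
Per-repeat seeds are derived substreams of the master seed, so a single
repeat is reproducible in isolation and the whole report is bit-identical
under the same seed. Stratification keeps per-fold class proportions within
one case of the population proportions. An optional case-group id keeps
replicate spectra of one patient inside a single fold
(`StratifiedGroupKFold`); by default replicates are treated as independent
cases. If a training fold selects no feature at all (possible in tiny or
null tables), that fold records no network and classifies by the training
majority class, with a warning.

## Synthetic data generator

The generator emulates a processed peak table, not raw spectra — no peak
shapes, baselines, or alignment artefacts. Default design (96 features,
200 cases per class):

- **Primaries** (5): class-conditional Gaussians whose class means differ
  by 2.0, 1.9, 1.8, 1.7, 1.6 within-class SD. Per-feature baseline means
  are uniform in [20, 200] intensity units with coefficients of variation
  in [0.15, 0.4].
- **Children** (7): each receives a per-case uniform fraction (0.3–0.7) of
  its parent primary plus independent Gaussian noise (0.3 of the parent
  SD); five sit at nearby m/z ("modifications"), two at exactly half the
  parent m/z (doubly charged ions).
- **Convolution pair** (1): 30% of a primary's intensity is moved into its
  m/z neighbour case by case, imitating overlap of adjacent peaks.
- **Hidden-fragment pair** (1): two observed features are tight fractions
  (0.7–0.9, additive noise 0.1 SD) of one *unobserved* diagnostic molecule
  (class separation 1.8 SD) — the latent-variable situation the method
  cannot represent but should degrade on gracefully (one fragment becomes
  first-level, the other its child).
- All remaining features are drawn from a single class-independent
  Gaussian. Intensities are truncated at zero after all mixing.

The generative law (m/z grid, per-feature means/SDs) is a function of the
spec seed alone; case draws use a separate stream, so a lockbox can be an
independent sample from the identical population.

**Effect-size choice.** With ~400 cases, 96 features and 100 permutations,
the 3.2× threshold lands near 0.22–0.23 bits. The max-MI score of a
Gaussian marker separated by d SD is roughly 0.19 bits at d = 1.2, 0.27 at
1.4, 0.35 at 1.6, 0.47 at 2.0 (means over draws; draw-to-draw SD ≈ 0.03).
A marker at the bottom of the 1–2 SD band therefore sits *below* the
detectability floor of this protocol at this sample size — it cannot be
recovered stably by any tuning of the pipeline, only by more cases or a
lower multiplier. The default primaries are accordingly placed at 1.6–2.0
SD, the regime of the strongest markers in a real profiling study, where
the weakest primary clears the threshold by ≈ 3 draw-SDs. Passing
structure-recovery tests consequently show that clearly diagnostic markers
are found stably and that null features are rejected; they say nothing
about markers near the detection floor, where the method (by design of its
threshold) abstains.

What the generator does **not** model: heavy-tailed or multimodal
intensity distributions, m/z-dependent noise, missing peaks, batch and
drift effects, correlated noise between adjacent features beyond the single
convolution pair, and replicate structure. Results on it bound what the
method can do under ideal Gaussian conditions, not what it will do on
instrument data.

## Numerical and statistical choices

- Class labels map to integer codes in first-seen row order for tables,
  sorted order inside the sklearn estimator (`np.unique` convention); the
  positive class defaults to the second label.
- MI values are clipped at 0 to absorb −1e-16-scale round-off.
- The lockbox-consistency check compares the frozen-classifier lockbox
  error to the CV mean within 3 SD, where the SD combines the CV
  repeat-to-repeat scatter with the binomial uncertainty of the finite
  lockbox, √(sd_cv² + p(1−p)/n_lock): the repeat scatter alone measures
  fold-resampling noise and understates the sampling error of a few
  hundred withheld cases.
- Problem sizes in the test suite: the stability fixture uses 25 repeats
  (250 networks) of the default 400×96 table; the lockbox-consistency
  check runs 20 generator seeds at 24 features with 5 repeats and a
  50-permutation baseline; the serial-chain property uses 200 seeds at
  n = 1000. The acceptance script runs the full 100-repeat protocol.

## Known limitations

- The threshold multiplier 3.2 is empirical; there is no principled
  default, which is why the sweep utility exists.
- Hidden variables and third-level structure are out of the method's
  representational reach; the fragment-pair behaviour is a degradation
  mode, not a detection capability.
- The permutation baseline's global (pre-CV) computation sees the whole
  training table, so it is not a strictly nested estimate; boundaries and
  CPTs, the quantities that drive classification, are strictly
  fold-nested.
- Empirical MI on 3×2 tables is biased upward at small stratum sizes;
  because the same estimator is used for data and null, the screening
  comparison is fair, but reported MI values should not be read as
  unbiased dependence strengths.
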