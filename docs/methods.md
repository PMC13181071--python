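# Methods

## Problem setting

Binary screening for diabetic retinopathy: each fundus image gets a label
0 (No_DR) or 1 (DR), and each of *m* base classifiers emits a class-1
probability (and optionally the raw two-class logit pair behind it).
`drfuse` treats the classifiers as black boxes and operates purely at the
decision level: its inputs are an *n × m* probability panel, a label
vector, and — for the preprocessing path — 8-bit raster images.

## Fusion operators

Hard voting thresholds each classifier at `vote_cut` (default 0.5, ties
voting positive, matching argmax on a two-class softmax) and reports the
positive-vote fraction, so the fused score lives on {0, 1/m, …, 1} and a
downstream threshold τ turns it into a tunable majority rule. Soft voting
averages probabilities; the weighted variant uses weights
`ω_j = Score_j / Σ Score_k` derived from each classifier's test
performance (accuracy by default; AUC or F1 selectable). Soft and
weighted voting share one arithmetic kernel so the uniform-weight case
reduces to soft voting exactly, not merely to rounding error.

Rank-based fusion replaces each classifier's scores by fractional ranks
within the evaluated batch (average rank on ties), normalized to (0, 1]
by dividing by *n*, and averages them. This makes the rule invariant to
any strictly increasing per-classifier rescaling — useful when the base
models are differently calibrated — at the cost of batch dependence: a
sample's fused score depends on which other samples are scored with it.

### λ-fuzzy measure and the fuzzy integrals

Classifier importances are fuzzy densities `g_i ∈ [0, 1]`; subsets
combine through `μ(A∪B) = μ(A) + μ(B) + λ μ(A) μ(B)`. Requiring
μ(full set) = 1 pins λ to the unique non-trivial root of
`1 + λ = Π_i (1 + λ g_i)` on (−1, ∞): λ > 0 when Σg < 1 (redundant
classifiers), λ < 0 when Σg > 1 (complementary), λ = 0 when Σg = 1
(additive). The solver brackets the root by sign and uses Brent's method
(`xtol ≤ 1e−14`); the resulting measure is checked to satisfy
μ(full) = 1 within 1e−6 and subset evaluation uses the closed form
`μ(S) = (Π_{i∈S}(1 + λ g_i) − 1)/λ`. Density vectors that cannot reach
μ(full) = 1 (all zeros, a single sub-unit density, sums > 1 with a
density equal to 1) are rejected as invalid.

The Choquet integral sorts a sample's scores ascending (`a_1 ≤ … ≤ a_m`,
`a_0 = 0`) and accumulates `Σ (a_i − a_{i−1}) μ(A_i)`, where `A_i` is the
set of classifiers at sorted positions i…m. The Sugeno integral is the
max–min counterpart `max_i min(a_i, μ(A_i))`. Both are computed with a
vectorized suffix recursion `μ(S∪{j}) = μ(S) + g_j + λ μ(S) g_j` (O(nm));
ties in the sort are harmless because tied increments vanish (Choquet)
and tied min/max terms coincide (Sugeno), which the suite asserts by
permuting tied columns. Because the fuzzy densities used in published
ensemble experiments are typically not reported, two presets are
provided: `additive` (performance scores normalized to Σg = 1, λ = 0)
and `sub-unit` (the same scaled by `density_sum`, default 0.8, giving
λ > 0 — the natural prior for highly correlated CNN backbones).

Average-logit fusion averages the raw logit pairs elementwise and
applies the two-class softmax, computed as `sigmoid(l̄_1 − l̄_0)` for
numerical stability.

## Thresholding and metrics

Predictions are `score ≥ τ` (inclusive, so τ = 0 predicts all positive).
`optimize_threshold` evaluates the objective (F1 by default; balanced
accuracy or accuracy selectable) on the grid {0, step, …, 1}
(step = 0.01) and returns the smallest maximizer — the recall-favoring
tie-break appropriate for screening. Threshold selection on the
evaluation labels mirrors common practice in retrospective comparisons;
for new studies a separate tuning split should be passed instead (the
API takes any labels/scores pair, so this is a caller decision).

Confusion matrices follow the row convention `[[TN, FP], [FN, TP]]`.
Metrics are percentages: accuracy, precision, recall (sensitivity),
specificity, F1, balanced accuracy = (recall + specificity)/2; zero
denominators yield 0 (so a degenerate all-negative predictor reports
0.00 precision/recall/F1 rather than NaN). Values are kept at full
precision internally and rounded to 2 decimals only in display fields.
ROC-AUC is the Mann–Whitney statistic `U/(n⁺ n⁻)` with midrank ties,
identical to the trapezoidal area under the empirical ROC curve; the
suite cross-checks it against a brute-force pairwise oracle and
scikit-learn.

## Calibration diagnostics

Per-class score densities use a Gaussian KDE with Scott's-rule bandwidth
`h = sd · n^{−1/5}` on a 512-point grid spanning at least [−0.2, 1.2]
(widened by 4h beyond the data range so the density integrates to ~1 on
the grid; a zero-spread class falls back to h = 1e−3). The decision
margin is `P5(DR scores) − P95(No_DR scores)` — a percentile
operationalization of the visual gap between the two density bumps; it
is negative under overlap and invariant to common shifts. Margins are
binned into `excellent` (> 0.4), `moderate` (0, 0.4] and `severe` (≤ 0);
the cut-offs reflect the empirical regimes reported for voting-style
versus fuzzy-integral ensembles (wide 0.4–0.6-unit margins versus
compressed ~0.2-unit ranges versus near-overlap) and are configurable.

## CLAHE

`clahe_gray` partitions the image into a `tile_grid` of tiles (edge
replication pads ragged sizes, cropped back afterwards), computes each
tile's 256-bin histogram, clips it at
`max(1, clip_limit · tile_area / n_bins)` — the relative convention that
makes clip 2.0 mean "twice the mean bin height" independent of tile
size — redistributes the clipped excess uniformly in one pass (exact
mass conservation; bins may marginally exceed the limit afterwards), and
equalizes via `LUT(v) = round(255 · CDF(v))`. Each output pixel is the
bilinear blend of the four nearest tile-center LUTs, clamped at borders,
which eliminates tile seams. With a 1×1 grid and an unbounded clip the
procedure reduces to global histogram equalization, which the suite
verifies. Color images are enhanced on the BT.601 luma
(`Y = 0.299R + 0.587G + 0.114B`); the luma delta is added to all three
channels, leaving chroma offsets untouched except where the final clip
to [0, 255] saturates. Defaults (clip 2.0, 8×8 tiles, bilinear resize to
224×224 applied after enhancement) match the fundus-preprocessing
configuration the toolkit targets; enhancement-before-resize is the
default order and both are configurable.

## Synthetic data

`simulate_panel` draws a label vector with a deterministic positive
count (`ceil(prevalence · n)`), then per sample couples the *m*
classifiers through a Gaussian copula with exchangeable correlation
`rho` and maps the latent uniforms through class-conditional Beta
inverse CDFs, so each classifier's marginal operating point is exact by
construction regardless of the coupling. Logits are reconstructed as
`(0, logit(p))`, the canonical softmax-equivalent pair.

The `aptos_like` preset fixes the conditions the toolkit is exercised
under: n = 733 with 372 positives / 361 negatives, m = 4,
per-classifier sensitivity 0.99 and specificity 0.98 at the 0.5 cut,
rho = 0.6. The Beta family is deliberately *saturated*: positives
~ Beta(a, 0.25) with a solved so P(p ≥ 0.5) = 0.99, negatives
~ Beta(0.25, b) solved so P(p < 0.5) = 0.98. The outer shape 0.25 piles
mass against the endpoints, emulating the strongly bimodal softmax
outputs of well-trained CNNs; flatter families satisfy the same
operating point but understate score separation and would not reproduce
the wide-margin calibration regime of real voting ensembles. rho = 0.6
encodes that backbones trained on the same data err on overlapping hard
cases. `stratified_split` takes `ceil(fraction · class size)` per class,
reproducing the 361 + 372 = 733 test arithmetic from the 1805/1857
breakdown. `panel_from_confusion` inverts a printed confusion matrix
into a single-classifier panel whose 0.5-threshold evaluation returns
exactly that matrix — used to recompute published metric rows.
`simulate_fundus` renders a low-contrast retina-like RGB image (circular
field of view, radial shading, optic disc, vessel arcs, bright/dark
blobs) for CLAHE tests; it is a statistical stand-in, not a
photorealistic fundus.

What passing tests on these panels show — and what they do not: the
generator reproduces marginal operating points, inter-classifier
correlation, prevalence and score bimodality, so it exercises every
fusion/threshold/calibration code path under realistic geometry. It does
not model per-image difficulty structure, calibration drift between
training and deployment, label noise, or the 5-grade severity
distribution, so simulated accuracies (≈ 99.7 % for soft voting) sit
above what trained CNNs achieve on real data (≈ 98.6 %) and should be
read as properties of the simulation, not performance claims.

## Problem sizes and numerics

Default test-suite sizes: 733-sample panels for end-to-end checks,
10 000 samples for operating-point recovery (99 % binomial intervals)
and correlation checks, ≤ 160×160 images for CLAHE; the whole suite runs
in a few seconds on one core. Grid search uses step 0.01; λ solving uses
bracketed Brent iterations; fused-score and report serialization is
fixed-precision (6 decimals) with sorted JSON keys, making CLI outputs
byte-reproducible for a fixed seed.

## Known limitations

Fusion of two-class problems only (no 5-grade severity); fuzzy measures
are supplied or preset-derived, not learned from data; no confidence
intervals or significance tests between fusion methods; no recalibration
(Platt/isotonic) — the KDE module diagnoses calibration but does not fix
it; CLAHE is 8-bit only.
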