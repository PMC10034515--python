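# Methods

This note records the models, estimators, numerical choices and known
limitations behind `cmpens`, in the order data flows through the package.

## Synthetic scenes and CMP stacks

`synthetic_data.generate_micrograph` emulates the *statistics* of H&E
nucleus micrographs, not their appearance: non-overlapping random ellipses
(default radii 5–11 px) are placed by rejection sampling until a foreground
fraction target is met (default 0.15, below the 0.5 cap so that true
negatives dominate, as they do in real micrographs where roughly 18% of
evaluated pixels are nuclear), then colored with a two-class mean-color
model (nucleus purple vs. eosin pink) plus smoothed Gaussian texture of
amplitude 0.035.  It does **not** model touching/overlapping nuclei, stain
variability across scanners, chromatin texture, or out-of-focus blur —
passing tests on these scenes demonstrate the correctness of the pipeline's
machinery, not segmentation performance on real tissue.

`generate_cmp_stack` builds per-pixel ensembles around a base probability
map p₀ = logistic(sharpness · signed boundary distance), so p₀ = 0.5 exactly
on object boundaries.  Member values are clip(p₀ + eᵢ, 0, 1) with i.i.d.
noise eᵢ from one of three families: Gaussian; *skewed* — a shifted/scaled
Beta(2, 5), bounded and with controllable skew sign, chosen over unbounded
skewed draws because CMPs live in [0, 1]; or symmetric alpha-stable
(default α = 1.7) for heavy tails.  The clipped fraction is recorded per
pixel so distribution-shape tests can exclude saturated pixels.  Defaults
(M = 100 members, noise scale 0.08, sharpness 1.0) give narrow unimodal
histograms away from boundaries and ambiguous ones in the boundary band,
the regime in which fusion-rule comparisons are meaningful.

## Aggregation rules

Mean, median and alpha-location produce probability maps binarized at a
threshold (default 0.5; a value exactly at the threshold maps to
background).  Majority vote is binary directly: foreground iff strictly
more members report pᵢ > 0.5 than pᵢ ≤ 0.5; exact 50/50 ties vote
background, and the unanimous-foreground corner (where the vote *ratio* has
a zero denominator) votes foreground.  The median is the standard
order-statistic median — for even M the midpoint of the two central order
statistics — since only the true median delivers the robustness to skewed
histograms that motivates the rule.

Alpha-location fits a stable law per pixel (below) and takes its location
μ, clipped to [0, 1] since CMPs are probabilities.  Two per-pixel failure
modes fall back to the sample median with a logged warning: a fitted
location outside the observed sample range, and a dominant repeated value
(> 40% tied samples).  Both mark the stable model as inapplicable — stable
laws are continuous with full support, while heavily clipped synthetic
histograms carry a point mass at 0 or 1.  Degenerate (constant) pixels
return their common value.

## Alpha-stable representation

Parameterization: φ(ω) = exp(−γ|ω|^α [1 − i sign(ω) β tan(απ/2)]) · exp(iμω)
for α ≠ 1, with the logarithmic branch at α = 1.  Note γ multiplies
|ω|^α, so the equivalent scale of `scipy.stats.levy_stable`'s S1
parameterization is γ^(1/α); the conversion is round-trip tested, and the
α = 2 special case has variance 2γ.  Densities come from scipy's numerical
characteristic-function inversion.

Estimation is an iterative regression on the empirical characteristic
function (ECF), in the spirit of Koutrouvelis' classical procedure:

1. standardize by median and half-IQR (the quantile-based initialization);
2. regress log(−log |φ̂(t)|²) on log t over t = kπ/25, k = 1..12, giving α
   (clamped to [0.3, 2]) and the standardized scale;
3. regress arg φ̂(u) on (u, u^α) over u = kπ/50, giving μ and β (clamped to
   [−1, 1]; near α = 1 the logarithmic design column replaces u^α, and β is
   reported as 0 when α is within ~0.03 of 2, where it is unidentifiable);
4. fold the estimates into the standardization and repeat (2 passes).

The estimator is deterministic, needs no lookup tables, and vectorizes over
thousands of pixels at once (the per-pixel aggregation path).  An optional
Nelder–Mead polish of the ECF least-squares distance (`FitConfig(refine=True)`)
is available but off by default; the regression alone recovers μ of a
Gaussian to ~2·10⁻⁴ and α of a Cauchy to ~10⁻³ at n = 10⁵.  Fits use the
raw member values, never binned counts.  Shapiro–Wilk normality checks
(`gaussianity_test`) subsample reproducibly above n = 5000, the statistic's
specified range.

## Metrics

ACC and DC are the standard confusion-count forms.  The continuous accuracy
is implemented as cACC = [Σaᵢbᵢ + Σ(1−aᵢ)(1−bᵢ)]/N, which is bounded in
[0, 1] and reduces *exactly* to ACC for binary inputs; the sign-corrupted
difference form seen in print (it simplifies to (Σa + Σb − N)/N,
independent of elementwise agreement) is available behind `literal=True`
for audit only.  The continuous Dice default is the foreground-weighted
Σaᵢbᵢ/Σaᵢ (recall-like for binary inputs) with the symmetric soft Dice
2Σaᵢbᵢ/(Σa + Σb) as an option, since published cDC values cannot be
attributed to one form with certainty.  Report tables round to 3 decimals,
half-to-even.

A pooling identity matters for reproducing published tables: with equal
per-image pixel counts, mean-of-per-image-ACC equals pooled-count ACC
exactly; the analogous identity fails for Dice.  The shipped benchmark
contingency table (7 × 62 500 pixels per row) reproduces the published ACC
column through this identity, while its pooled Dice (0.8104 for the best
mean-fused ensemble) intentionally differs from the published per-image
average (0.792) — a different statistic.

## Patch classifier

The canonical network is the ten-layer stack described in the README
(three valid-mode conv/ReLU/dropout/maxpool blocks of 25/50/80 filters with
4/5/6 kernels and dropout 0.1/0.2/0.25, two dropout-0.5 dense-1024 layers,
2-way softmax).  The last 2×2 pooling uses ceil semantics (5 → 3).  Standard
counting gives 1 966 559 trainable parameters; the nominal parameter count
quoted alongside the original architecture (915 934) is inconsistent with
its own layer table and is treated as metadata, never asserted.

Forward pass, backpropagation, dropout (inverted scaling), Adam and
early stopping are implemented directly on numpy (im2col convolutions via
`sliding_window_view`, float32 throughout); no deep-learning framework is
required, and the weight tensors stay directly addressable for pruning.
Training uses a seeded 70:30 train/validation split, cross-entropy loss,
Adam at 10⁻³ (desk-scale runs use 3·10⁻³), early stopping on validation
loss with patience 5 and an epoch cap (30 default), restoring the
best-validation weights.  Initialization is Glorot-uniform from the model
seed; all randomness (init, shuffling, dropout) is generator-seeded, so
identical seeds reproduce identical weights bit for bit.

Dense prediction slides the patch over valid centers (rows/cols
25..H−26) subsampled by a stride.  The published evaluation geometry —
62 500 pixels per 1000² image at stride 4, i.e. ceil(1000/4)² — implies
prediction at *every* stride-th pixel; `predict_cmp(..., full_grid=True)`
reflection-pads by half a patch to reproduce it, while the default predicts
only fully valid windows.  Grid origin, stride and patch size are recorded
on the output.

### L1 filter pruning

For each conv layer, filters are ranked by the L1 norm of their kernel
weights; the round(f·N) smallest (round half-up; ties removed lowest index
first; at least one filter always kept) are deleted together with the
successor conv layer's matching input channels.  Pruning the last conv
layer removes the matching features of the first dense layer under
*channel-major* flattening (activations are transposed to channel-first
before flattening, so each channel owns a contiguous feature block); this
mapping is exercised by a zero-filter invariance test (pruning zero-weight
filters with zero biases leaves every prediction unchanged).  Note that at
0.5% fraction granularity successive fractions can remove identical filter
counts — parameter counts are non-increasing in f, and strictly decreasing
only across coarser fraction steps.

## Ensemble recipes and desk scale

Eight recipes cross member-diversification strategies (random seeds ×
three training sizes; a shared-seed pruning schedule of n·0.5% for member
n, spanning 0.5%–50% in 100 distinct steps, × three training sizes; a
training-size ladder from 1000 to 420 000 samples; the ladder with fixed
80% pruning).  Fixed training sizes are defined as 0.1/1/10% of the
architecture's own trainable-parameter count, so the compact desk-scale
model (8/12/16 filters, dense 64/64, ~23 300 parameters) trains on ~23/233/
2330 patches by the same logic.  Member seeds derive from the base seed via
a counter scheme recorded in provenance, so any member can be retrained in
isolation.  Pruned-schedule ensembles share one initialization (and one
pretraining checkpoint when pretraining is enabled) — member diversity then
comes from pruning alone.

The desk-scale end-to-end experiment (`io_cli.run_desk_scale_experiment`)
uses three 128² training scenes, one 160² test scene, the compact
architecture, 8 members, 3 epochs at learning rate 3·10⁻³, and stride-4
prediction (~784-pixel evaluation grid).  These sizes were chosen once as
the smallest configuration in which ensemble variance reduction is reliably
visible above sampling noise; scaling up to the 100-member study is a
configuration change, not a code change.

## Known limitations

* The ECF-regression stable fit assumes unimodal, atom-free samples; the
  aggregation path guards against clipping-induced point masses by falling
  back to the median, but extremely small ensembles (M < ~20) make all four
  stable parameters noisy and the alpha rule then leans on its fallback.
* The numpy CNN is single-threaded BLAS-bound; it is meant for desk-scale
  ensembles (tens of members, thousands of patches), not for GPU-scale
  training on full micrograph collections.
* Synthetic-scene results bound correctness, not real-data performance; no
  claim is made about absolute accuracy on stained tissue.
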