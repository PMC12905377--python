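# Methods

## Recording model and time grid

A recording is a cells × frames matrix of ΔF/F₀ values on a shared
`TimeGrid`: 1500 frames at 2 Hz (12.5 min), with the hormone bath applied
on frames [600, 960) and washout after.  Windows are half-open frame
ranges: BASAL = [0, lh_start), LH = [lh_start, lh_end),
WASH = [lh_end, n_frames).  A grid with `lh_start == lh_end` encodes a
basal-only recording (produced by `truncate_basal`); such a matrix cannot
be truncated again, since it has no ligand window left.

ΔF/F₀ is computed per cell as (F(t) − F₀)/F₀ with F₀ the mean raw
fluorescence over the basal window.  This assumes a flat baseline; users
with drifting real data should normalize upstream and feed ΔF/F₀
directly.  A cell whose basal mean is ≤ 0 raises an error naming the row.

"Total change" per window is the per-frame mean ΔF/F₀ — chosen over the
raw sum so that the 600-frame basal window and the 360-frame application
window are directly comparable; the raw sum rides along as a secondary
column.  AUC is the trapezoidal integral over the frames of the window
with time in seconds; with half-open windows the three window AUCs differ
from the whole-trace AUC by exactly the two boundary-crossing trapezoids
(asserted in the tests).  A cell is "inactive" in a window if its maximum
ΔF/F₀ there is below 0.1 — a maximum, not a mean, because a single
suprathreshold transient makes a cell a responder.  Heatmap ordering
sorts cells by LH-window total change, descending, ties broken by row
index so the order is a deterministic permutation.

## Synthetic cohorts

Each trace is the sum of a basal component present in every cell and a
hormone-response component present only in a per-cell Bernoulli
responder subset:

- **Basal**: one sinusoid with per-cell frequency drawn uniformly from a
  group-specific band and random phase, plus a Gaussian random-walk drift
  scaled so its typical excursion is `drift_amp`, plus iid Gaussian
  noise.  This is the simplest process that gives cells individual
  spontaneous signatures a classifier can exploit.
- **Response**: saturating rise `A(1 − exp(−(t − onset)/rise_tau))`
  beginning at `lh_start + latency`, plateau through the application
  window, exponential decay with `decay_tau` after washout begins.
  Amplitude and latency are truncated normals (at 0) per cell.  A cell
  whose onset falls after the application window contributes no response.

Generation is bit-reproducible given (config, seed); labels and
round-robin animal ids are bookkept per cell.  Latency and time constants
are in seconds and converted through the grid rate, so configurations are
grid-independent.

### Default parameters and calibration

Defaults are calibrated (average over realizations at the default cohort
sizes, 278/175 male and 401/203/391 female cells) to the published group
summaries: male Het/Hom mean-trace peaks 0.40/0.23; female
Het/Hom/treated peaks 0.28/0.055/0.32; and first-hormone-minute inactive
fractions ≈16.5% (Het) vs ≈37% (treated).  The structural choices behind
the numbers:

- Male genotypes differ in responder fraction (0.85 vs 0.70), response
  amplitude, and kinetics (Het: fast onset, slow decay; Hom: delayed,
  sluggish rise, fast decay), with *overlapping* basal oscillation bands
  — basal carries genotype signal but less than the response, so
  full-trace classification dominates basal-only classification.
- Female Hom cells are mostly non-responders (responder fraction 0.15),
  matching their nearly flat mean trace.  Female genotype basal bands are
  disjoint, and the treated group shares the control band: in this cohort
  the spontaneous signature is the phenotype the rescue restores.
- Female Het latency is broad (15 ± 25 s truncated at 0).  This matters
  for transfer: if every control cell responded within seconds, response
  *onset time* would become the genotype feature and the delayed treated
  cells (latency 49 ± 24 s, slow rise — which produces the ≈37% inactive
  first minute) would be pushed to the mutant class.  With a broad
  control latency distribution, the learned genotype evidence is
  "a response exists" plus the basal signature, both of which treated
  cells share with controls — the regime in which transfer to the
  control class is the correct generalization.

The calibration targets are recorded in `PEAK_TARGETS` and
`INACTIVE_TARGETS`; `make_paired_config` builds two-group cohorts that
differ in exactly one component (response kinetics, basal dynamics, or
nothing) for the localization and chance-level analyses.

### What the generator does not emulate

No biophysical calcium dynamics (no IP₃/store machinery), no
photobleaching, motion artifacts, or segmentation errors, no within-animal
correlation (animal ids are bookkeeping, not a random effect), and no
heavy-tailed amplitude distributions.  Passing tests therefore show that
the analysis machinery recovers structure that is present by
construction; they do not certify performance numbers on real recordings.

## Embeddings

`embed_pca` is the first two principal-component scores (scikit-learn,
full SVD); a rank-deficient input zero-fills the second axis with a
logged warning.  `embed_umap` consumes umap-learn with a fixed
`random_state` and skips gracefully (returning None) if the
implementation is unavailable.

`embed_tsne` is an exact O(n²) t-SNE written for this package: per-point
Gaussian bandwidths found by binary search to match perplexity 30
(entropy in nats), symmetrized joint probabilities, Student-t map kernel,
and gradient descent for 1000 steps with learning rate 200, early
exaggeration ×4 for the first 100 steps, momentum 0.5 switching to 0.8 at
step 250, and adaptive per-coordinate gains — standard settings where the
source recipe is silent.  The per-step KL divergence is recorded against
the *unexaggerated* P so the objective trace is comparable across the
run; the final value never exceeding the first is asserted in tests.
Exact t-SNE is affordable at the cohort sizes used here (≤ ~1000 cells);
scikit-learn's implementation serves as an independent cross-check in the
test suite, not as the implementation.

## Clustering

K-means is the classic Lloyd iteration: random initial centroids chosen
among the data points (k-means++ available as an option), assignment by
squared Euclidean distance with ties to the lowest cluster index, mean
update, stop when assignments stabilize.  Ten seeded restarts, best by
inertia; an emptied cluster is re-seeded from the point farthest from its
centroid.  Inertia is non-increasing across iterations (asserted).  The
same operation runs on 2-D embeddings and on raw 1500-dimensional traces
(full-dimensional clustering).

Silhouette: a(i) is the mean distance to the point's own cluster
excluding itself, b(i) the smallest mean distance to another cluster,
s(i) = (b − a)/max(a, b); singleton clusters score 0 (common convention);
cluster scores are means over members.  Composition tables are
row-normalized cluster × group fraction matrices; purity is the row
maximum.

## Classification

The stratified 80:20 split draws round(0.2·n_class) test cells per class
from a seeded permutation; train and test are disjoint and exhaustive
(asserted).  Early stopping for the feature net monitors a further
stratified 10% carve-out of the training set — the test set never
influences stopping.  Among epochs with equal validation accuracy the
*latest* weights are kept (patience counts strict improvements only):
on easily separable cohorts validation accuracy saturates immediately,
and keeping the epoch-0 weights would leave the network essentially
untrained, which degrades both the z₂ feature space and any saliency
analysis.  `max_epochs` defaults to 500; early stopping dominates in
practice.

The network is implemented directly in NumPy — He initialization,
inverted dropout, explicit backpropagation, Adam (β₁ 0.9, β₂ 0.999,
ε 1e-8) — which keeps the hidden activations and class gradients needed
for feature extraction and saliency explicit.  Class labels are encoded
HET = 0, HOM = 1, HOM_TREATED = 2, and argmax ties resolve to the lower
index, so reports are deterministic.

Inputs are raw ΔF/F₀ vectors with no per-feature standardization (none is
described in the source recipe); a `standardize` flag exists for the
scale-sensitive baselines and is off by default.  The multi-layer
perceptron baseline width is a parameter defaulting to 400 units (the
headline configuration; 100 is the alternative printed value).

Transfer evaluation feeds held-out-group cells through the binary
Het/Hom model and reports the percentage whose argmax class is HET.
Accuracy and macro-F1 come from scikit-learn and are re-derived by a
hand-written confusion-matrix oracle in the tests.

On the default female cohort the basal-only network can outscore the
full-trace network: with disjoint basal bands the 600-frame problem is
nearly separable, while on 1500 inputs training tends to latch onto the
larger-amplitude response features first.  The male default (overlapping
bands) shows the expected ordering — full-trace ≥ basal-only — and is the
cohort on which that property is asserted.

## Saliency

Grad-CAM's activation-weighting was designed for convolutional feature
maps.  For this dense network the first hidden layer was the natural
"feature map" candidate, with relevance redistributed to frames via the
normalized static weight magnitudes |W₁[k,t]|/Σ_t|W₁[k,t]| — but that
redistribution provably cannot localize here: under Adam every weight
moves with similar step magnitudes, so the first-layer magnitude profile
stays flat no matter how long training runs, and the resulting maps are
near-uniform.  It is retained as `method="static_weight"` for
illustration.

The default map is the class-score sensitivity r_t = |(∂y_c/∂x)_t|,
max-normalized per cell, computed with dropout disabled and, by default,
against the model's predicted class.  Signed and unsigned
gradient-times-input variants (`grad_x_input`, `input_gradient`) are also
provided; they emphasize frames with large signal, which localizes
response-window differences well but inverts on basal-only differences
(the small-amplitude basal frames are down-weighted by the x factor).
The sensitivity map localizes in both paired designs, which is why it is
the default.  The localization score is the mean relevance inside a
window divided by the mean relevance outside it.

## Pipeline

`run_full` executes simulate → metrics/heatmap → PCA/t-SNE/UMAP →
K-means (K = 2…5, embedded and full-dimensional) → baselines + feature
net (full and basal-only) → transfer → saliency → JSON report.  Stage
seeds derive from one master seed as crc32("{seed}:{stage}") mod 2³¹, so
stages are decoupled but the whole run is reproducible; reruns produce
byte-identical CSV tables (asserted on a smoke cohort).  The report's
feature-net accuracy is re-derived from the persisted predictions before
the run completes.

## Problem sizes

Unit tests run on short grids (300 frames) and small cohorts (tens of
cells per group); the calibration, transfer, chance-level, and
localization analyses run at the default cohort sizes (453 male, 995
female cells) over 3–5 seeded repetitions, and the acceptance script
averages cohort-level quantities over 3 realizations — sizes at which the
exact t-SNE and the NumPy network train in seconds to a few minutes on
one CPU.

## Known limitations

- The generator's group differences are stylized (bands, latencies,
  responder fractions); real recordings mix many more sources of
  variation, and classifier accuracies here say nothing quantitative
  about real data.
- The basal-only separability of the female default cohort is by
  construction (disjoint bands) and stronger than one should expect in
  practice.
- t-SNE is exact but O(n²); beyond a few thousand cells a
  Barnes-Hut/FFT implementation should be substituted.
- Chance-level assertions use per-cohort 95% binomial intervals; at fixed
  seeds they are deterministic, but near-boundary values can move if the
  generator or training recipe changes.
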