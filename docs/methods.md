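# Methods

This note documents the model, the numerical choices, the synthetic-data
generator and the limits of what the bundled tests demonstrate.

## Dynamic connectivity construction

A subject is an R×M matrix of ROI-level BOLD series. Windowing uses a
0-based half-open convention: window k covers time indices [k·s, k·s+L),
and K = ⌊(M−L)/s⌋ + 1 full windows are taken; trailing points that do not
fill a window are dropped. With the defaults L=30 and s=2 a 137-point scan
yields 54 windows. Subjects shorter than L are rejected, never padded.
A helper discards initial volumes acquired before magnetisation equilibrium
(conventionally 3 of 140, retaining 137).

**Low-order FC** is the within-window Pearson correlation (window means
subtracted). If a region is constant inside a window its correlations are
undefined; they are set to 0, the diagonal to 1, and a warning is logged.

**High-order FC** is the similarity between connectivity *profiles*: entry
(i,j) of window k is the cosine of columns i and j of that window's
low-order matrix, computed on the raw columns (diagonal included, no mean
centring). A Pearson-style variant that centres the columns first is
available as `high_order_centered` for sensitivity analysis; the default is
the plain inner-product form. Zero-norm columns fall back to similarity 0.

## Edge selection

Each undirected edge is reduced to one scalar per subject — its FC averaged
over the K windows — and tested with a pooled-variance two-sample two-tailed
t-test between groups; edges with p < 0.05 (configurable) are kept. The
per-subject average is used because per-window values of one subject are
strongly autocorrelated and would not be independent samples; stacking all
windows is available (`per_window_stack`) but not the default, as is Welch's
unequal-variance test (`welch`). No multiple-testing correction is applied:
the threshold is a feature-selection dial, not an inference claim. Edges
with zero pooled variance get p = 1.

The mask is fitted **on training subjects only** and frozen before any
validation or test subject is touched; the pipeline splits subjects before
mask fitting, and a test asserts held-out subjects never enter the fit.
One mask is fitted per FC order.

## Node features and the propagation operator

Both the clustering coefficient and the graph convolution consume
connection *strength*, so negative correlations are rectified first:
absolute value by default, or hard zeroing via `negative_policy=clip_zero`.
(Fractional powers and D̃^{−1/2} are undefined for negative weights.)

The weighted local clustering coefficient uses the geometric-mean triangle
intensity with weights normalized to [0,1] by the window's maximum
off-diagonal |weight|:

    nᵢ = 2/(kᵢ(kᵢ−1)) · Σ_{j<h ∈ 𝒩ᵢ, w_jh≠0} (ŵᵢⱼ ŵᵢₕ ŵⱼₕ)^{1/3},

where 𝒩ᵢ are the neighbours of i on the sparsified graph and kᵢ = |𝒩ᵢ|.
Nodes with fewer than two neighbours get 0. With all retained weights equal
this reduces exactly to the binary clustering coefficient, and the tests
cross-check the implementation against networkx's weighted clustering as
well as a brute-force triple enumeration. A single-neighbour-sum variant is
kept behind `eq3_literal` for comparison only; it is not a clustering
coefficient (it is unbounded) and is off by default.

The propagation operator per window is D̃^{−1/2}ÃD̃^{−1/2} with Ã = A + I on
the rectified, masked FC (zero diagonal before augmentation). Degrees are
always ≥ 1 because of the self-loop, and for nonnegative Ã all eigenvalues
of the normalized operator lie in [−1, 1].

## Classifier

Per window, graph-convolution layers H⁽ˡ⁺¹⁾ = ReLU(S H⁽ˡ⁾ W⁽ˡ⁾) with the
window's normalized adjacency S. Widths are 1 → 16 → 1 (two layers): the
scalar clustering coefficient enters per node and a scalar per node leaves,
so each window reduces to an R-vector and the per-window input and output
dimensions match. The GCN weights are shared across windows (per-window
weights would multiply parameters by K for no clear gain; a
`share_gcn_weights=False` mode exists). The K-step sequence feeds a 3-layer
LSTM (hidden size 64 by default) with the standard gate equations
(f, i, o sigmoid; candidate tanh; state C = f⊙C₋₁ + i⊙C̃; h = o⊙tanh C),
and the final hidden state feeds a single fully connected softmax layer.

Training minimizes cross-entropy plus an L2 penalty (5e-4) with dropout 0.5
(between LSTM layers and before the head), Adam at lr 1e-3, batch size 64,
up to 400 epochs, early stopping on validation loss with patience 40, and
restores the best-validation parameters. Subjects are split 70/15/15
(train/val/test), stratified by label. Arithmetic is single precision;
initialization, batch order, dropout and splits all derive from the config
seed, so a run is bit-reproducible on one machine.

**Initialization detail.** Node features and adjacencies are nonnegative,
so under ReLU any GCN channel whose weight starts negative is identically
zero *and has zero gradient* — it can never recover, and for the width-1
output layer this can kill the entire model at initialization. GCN weights
therefore start at |Glorot-uniform| values; training is free to push them
negative afterwards. LSTM/head weights use plain Glorot; LSTM forget-gate
biases start at 1. Everything else (backprop through the GCN, the LSTM and
the head, and the Adam update) is implemented directly on NumPy arrays and
verified against central-difference gradients in float64 (relative
agreement 1e-4 on a tiny model).

## Metrics and network ablation

TPR, TNR, PPV, NPV, ACC and F1 are computed from the confusion counts with
eMCI as the positive class and reported in percent; a zero denominator
yields NaN ("undefined") rather than an error.

Ablation of a resting-state network removes **all edges incident to its
regions** from the sparsified FC of every test subject, then recomputes
node features and normalized adjacencies before re-evaluating the already
trained model. Zeroing only node features would leave ablated regions
influencing message passing through their edges; removing the edges drives
the ablated regions' clustering coefficients to zero and updates their
neighbours' features consistently. The region→network table is user input
(two columns: 1-based region index, network label); no atlas grouping is
hard-coded.

## Synthetic cohort generator

The generator emulates what the pipeline actually consumes: ROI-level
series whose windowed correlation structure differs between groups on a
designated edge set.

* Each of `n_states` latent states (default 3) has a base correlation
  matrix built from a random sparse positive-weight graph, symmetrized and
  diagonally loaded to positive definiteness — this plants genuine
  triangles, so clustering-coefficient features carry structure.
* A sticky Markov chain (per-step switch probability 0.05 by default)
  selects the state at each time point; samples are zero-mean multivariate
  normal with the state's correlation matrix plus independent N(0, 0.25²)
  observation noise. The defaults give state dwell times of ~20 time points
  (slow connectivity fluctuation within a scan) and mild measurement noise
  that attenuates correlations by ≈6%.
* For the patient group, the correlation on each planted edge is shifted by
  the effect size (upward unless that would cross the positive-definiteness
  ceiling) in *every* state, and the shifted matrix is projected back to
  the nearest positive-definite correlation matrix by eigenvalue clipping
  (floor 1e-6). The group difference is therefore purely in connectivity,
  never in signal amplitude, matching what the classifier is supposed to
  detect.
* The cohort is a pure function of the spec: subject seeds derive
  deterministically from the cohort seed.

What the simulator does **not** model: haemodynamic response shape,
autocorrelated noise, scanner drift, motion or physiological confounds, and
site effects. Passing the bundled tests therefore demonstrates that the
pipeline recovers planted covariance differences under clean conditions and
is statistically calibrated under the null — not that it attains any
particular accuracy on real cohorts.

## Test problem sizes

The statistical suites run at reduced scale chosen to keep the full test
run in single-digit minutes on one CPU: null calibration pools ~10,200 edge
p-values from 37 cohorts (24 regions, 10 subjects/group); the
signal-recovery benchmark uses 5 cohorts of 120 subjects (30 regions, 137
time points, correlation shift 0.5 on 20 edges all inside one 8-region
synthetic "DMN" block — 8 regions are needed for 20 within-block edges).
At these sizes the mean held-out accuracy criterion (≥90%) and the
ablation ranking (the planted block is the most discriminative network) are
comfortably met.

## Known limitations

* Eigenvalue clipping is a projection heuristic; very large planted effects
  on dense edge sets can distort non-planted correlations slightly.
* The t-test selects each edge marginally; correlated edges enter or leave
  the mask together, and no FDR control is attempted by design.
* The high-order network default is the uncentered cosine of profiles;
  centred (Pearson) profiles can behave differently on near-constant
  columns — the switch exists precisely because the literature uses both.
* The NumPy training loop is single-threaded and CPU-bound; it is sized for
  cohorts of hundreds of subjects and ≤ a few hundred regions, not for
  voxel-level graphs.
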