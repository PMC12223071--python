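# Methods

This note documents the models and procedures implemented in `fedcaps`, the
defaults they ship with, and what the synthetic experiments do and do not
demonstrate.

## Scope and study conditions

`fedcaps` is a desk-scale, fully synthetic re-creation of a federated
brain-tumor detection pipeline for CT-like images.  Every experiment runs on
one CPU in minutes, on phantoms the package generates itself.  The default
problem sizes used throughout the benchmarks are: 64×64 phantoms; 200
training / 50 test scans for segmentation (5 epochs); a 50-feature table
with 300 rows for selection; 150 training / 60 test scans, 5 clients and 10
communication rounds for the federated runs; 10 seeds for the optimizer
benchmark and 5 seeds per robustness scenario.  These sizes were chosen as
the smallest at which each behaviour of interest (convergence, recovery,
robustness ordering) is stably measurable.

## Synthetic phantoms

A phantom is a piecewise-constant slice: background (0.05), an elliptical
brain (0.45, semi-axes 24×20 px), a dark CSF-like rim (2 px, background
intensity) separating the brain from a bright skull ring (0.95, 3 px), and
optionally a tumor blob (0.75) drawn strictly inside the brain, plus
additive Gaussian noise (σ = 0.02 by default) and clipping to [0, 1].  The
intensity ordering background < brain < tumor < skull is enforced.

Tumor "types" are geometric presets — (size scale, eccentricity, boundary
roughness) triples named glioma-like (large, irregular), meningioma-like
(round, smooth) and pituitary-like (small).  They carry no biology; they
exist to give federated clients heterogeneous data.  Blob boundaries are
star-convex Fourier perturbations of an ellipse, pruned to one connected
component.

The pseudo-modality channel applies a strictly monotone intensity remap
(default `sqrt`, brightening soft tissue) followed by a Gaussian blur
(σ = 0.8 px).  It produces a visually distinct but perfectly aligned second
domain — enough to exercise multimodal registration and the leakage rule,
but it is **not** a generative translation model: it cannot hallucinate
structure, shift anatomy, or introduce domain-specific artifacts.  Results
involving the pseudo-modality therefore say nothing about learned
cross-modality synthesis quality.

Per-scan seeds are derived by SHA-256 hashing the master seed with the scan
index, so any subset of a dataset is reproducible independently of
generation order.

The default federated cohort has five clients: glioma-heavy (70/30),
meningioma/pituitary (50/50), glioma-only (highly skewed), balanced (IID)
and pituitary-leaning (60/40).  Because the cohort is glioma-heavy in
aggregate, the federated experiments generate tumor types with a 50/25/25
glioma/meningioma/pituitary cycle and profiles claim only ~80% of the pool,
so the per-type draws stay feasible.

## Preprocessing

* **Erosion/dilation** use the standard set definitions with disk
  footprints (erosion: translated footprint fits inside the set; dilation:
  footprint intersects it).  Pixels beyond the image border belong to
  neither the set nor its complement, so the erosion/dilation duality holds
  exactly only away from the border; tests compare interior windows.
* **Skull stripping**: Otsu threshold → erosion (radius 2 disk) → largest
  connected component → dilation → hole filling, returning one component.
  The recipe relies on the dark rim separating brain from skull; a blank
  image yields an empty mask rather than an error.
* **Anisotropic diffusion** is the explicit Perona–Malik scheme on
  4-neighbourhoods with replicate boundaries: `I += λ Σ c(|∇I|) ∇I` with
  conduction `c = exp(−(|∇I|/κ)²)` (a rational `1/(1+(|∇I|/κ)²)` option is
  provided).  λ ∈ (0, 0.25] is enforced for stability; κ (default 0.1 in
  intensity units) separates gradients to smooth from edges to keep.  The
  divergence form conserves the global mean to machine precision.
* **Min-max normalization** is the standard affine map onto a target range;
  constant input is an explicit error, never silently zeroed.
* **Mutual information** is computed from a joint histogram (default 32
  equal-width bins) with base-2 logs.  **Rigid registration** maximizes MI
  by an exhaustive integer-shift grid (default ±8 px), then a
  golden-section search over rotation, then half-pixel shift refinement —
  deterministic and derivative-free.  MI makes the criterion robust to
  monotone intensity remaps, which is why the cross-modality pair registers
  as accurately as the same-modality pair.
* **Quality gate**: SSIM (Gaussian-weighted) and PSNR with peak 1.0;
  default thresholds 0.75 / 22 dB, both configurable.  Identical images get
  infinite PSNR and pass; a flat reference is an error.

## Segmentation network

A U-Net whose blocks are either residual (two BN-conv layers plus an
identity skip, 1×1 projection when channels change) or dense (each layer
consumes the concatenation of all previous outputs; a 1×1 projection fits
the block into the U-Net channel plan).  Encoder levels are
maxpool → block; the bottleneck is one more block; decoder levels are
2×2 transposed convolution → concatenation with the matching encoder
output → block; the head is a 1×1 convolution with a sigmoid.

The `tiny` preset (depth 3, base 8 channels, ~200k parameters) trains on
CPU in about a minute per 5 epochs over 200 64×64 phantoms.  A `paper-like`
preset (depth 4, base 32) exists for structural parity but is not exercised
by the test suite.

Training minimizes soft Dice loss `1 − 2Σpg/(Σp² + Σg² + ε)` with
ε = 1e−6 (the unsmoothed form divides by zero on empty masks); an optional
BCE term can be added via config.  The optimizer is Adam (default LR 3e−3
for the tiny preset).  On all-empty-mask images the Dice loss stays near 1
by construction, so the mean training loss plateaus near 0.5 at a 50%
tumor fraction even when tumor masks are learned almost perfectly —
held-out Dice is the meaningful metric.

The whole stack (convolutions via im2col, batch norm, pooling, transposed
convolutions) is a compact numpy implementation with explicit
forward/backward passes, verified against numeric differentiation at 1e−6
tolerance.  It is deterministic: same seed, same inputs, bit-identical
weights.

A `skip_enabled=False` switch ablates the residual identity path; the
single-image overfit benchmark shows the ablated twin reaching a strictly
higher loss, the optimization benefit skips exist for.

## Features

GLCMs are computed after min-max quantization of the ROI to N levels
(default 8), counting pairs whose *both* pixels lie in the ROI, for offsets
(0,1) and (1,0), symmetric by default, normalized to sum 1.  Scalar
features: contrast `ΣP(i,j)(i−j)²`, energy `ΣP²`, homogeneity
`ΣP/(1+|i−j|)`, and the standard correlation (undefined — explicit error —
when a marginal variance vanishes).  Because quantization is min-max,
adding a constant to the image leaves all texture features unchanged.

First-order statistics use population formulas (divide by N) and
non-excess kurtosis (Gaussian → 3).  Deep features are global average
pooling of the capsule classifier's backbone activations (32 channels for
the tiny backbone).  Fusion is the weighted concatenation
`[α·deep ∥ β·handcrafted]` (α = β = 1 by default); a weighted *sum* is
available only when the blocks have equal length, since the two blocks
generally differ in dimension and concatenation preserves both for the
selector to prune.

## Hybrid Gorilla–Badger optimizer

A population metaheuristic for continuous minimization.  Per iteration
every agent receives two greedy proposals:

1. **Exploration** (three branches on one uniform draw `rand`):
   uniform re-draw in the bounds when `rand ≥ p`; otherwise a move toward a
   random member `(r₂−C)·X_r + L·H` when `rand ≥ 0.5`; otherwise the
   difference perturbation `x − γ·r·L·(L·(x−X_r) + r₃·(x−X_r))` with
   `γ = 2·rand−1`.  The amplitude pieces follow the Gorilla-Troops
   conventions: `C = (cos 2r₄ + 1)(1 − t/T)`, `L = C·l` with `l ~ U[−1,1]`,
   `H = Z ⊙ x` with `Z ~ U[−C, C]`.
2. **Exploitation**: follow-the-silverback
   `δ·rand₁·(|x − x_sb| + x)` with `δ = sin(2.5 − t/T)` when `|C| ≥ β`,
   else the badger-style fight move `x_sb + F·rand₂·α·(x_sb − x)` with
   `α = 2e^(−t/T)` and a fair ±1 flag `F`.

Proposals are accepted only if they improve the agent, so the best-so-far
trace is monotone non-increasing.  Defaults: p = 0.03, β = 0.8, clipping to
bounds (reflection available).  Note the exploration gate direction (branch
1 fires when `rand ≥ p`): with small p exploration is dominated by uniform
re-draws, which greedy acceptance turns into a cheap global restart
operator while the exploitation moves do the converging.

**Feature selection** wraps the optimizer over [0, 1]^d: positions are
binarized at 0.5 into masks and scored by
`w·(1 − cv_accuracy) + (1−w)·(selected/total)` with w = 0.9; empty masks
are penalized with fitness 1.  The inner evaluator is a cross-validated
nearest-centroid classifier (3 stratified folds) — deliberately light so
the wrapper can afford hundreds of mask evaluations; any
`evaluator(mask) → accuracy` callable can replace it.  The reported
fitness *score* is `1 − fitness` (higher is better); the feature reduction
rate is `FRR = 100·(1 − selected/total)`.

## Capsule classifier

Primary capsules are formed by a linear map from the input features (or
from the pooled activations of a small residual backbone in image mode),
reshaped to (n_primary × primary_dim) and squashed with
`v = (‖s‖²/(1+‖s‖²))·s/‖s‖` (zero maps to zero).  Digit capsules receive
per-pair linear predictions `û_ij = W_ij u_i` and are aggregated by
routing-by-agreement: logits start at zero, couplings are a softmax over
parents, parents squash their weighted sums, and logits grow by the
agreement `û_ij·v_j` (3 iterations by default).  The predicted class is the
capsule with the largest norm; the norm is the confidence (always < 1);
ties break toward the lowest class index.

Training uses margin loss (m⁺ = 0.9, m⁻ = 0.1, λ = 0.5); BCE over capsule
norms is a config alternative.  For backpropagation the routing couplings
are treated as constants of the forward pass — the usual simplification;
with one routing iteration the analytic gradient is exact (verified
numerically), and with three iterations the approximation trains reliably
in practice.  Primary capsules are taken from the *pooled* backbone
features rather than pre-pool maps: at 64×64 with a tiny backbone the
pooled variant is far cheaper and the pooled activations are also exactly
the deep-feature block used by the fusion stage, keeping one tap point.

## Federated simulation

Single-process emulation of K clients (default 5) over T rounds (the
benchmark uses 10): broadcast the global flat weight vector → each client
trains locally (3 epochs, Adam) → independent dropout (rate 0.10) and
poisoning (rate 0.10, additive Gaussian noise with σ = 0.5 × weight RMS;
the magnitude is a package choice, config-exposed) → optional client-level
differential privacy (clip to an L2 ball, add Gaussian noise with
σ = clip·√(2 ln(1.25/δ))/ε; defaults ε = 1, δ = 1e−5) → FedAvg
`w = Σ (n_k/N)·w_k` → ledger append → held-out evaluation.  Contributions
are summed in client-id order, making aggregation invariant to arrival
order.  If every client drops out, the round is skipped and the previous
global weights are retained.

Only `ClientUpdate` values (weights, sample count, scalar metadata) cross
the client/server boundary — the aggregator cannot see data by
construction, and an architectural test pins that interface.  With one
client and no failures the loop reduces exactly (bit-for-bit) to
sequential centralized training, which the tests verify.  Local Adam state
restarts every round, so the federated default LR (3e−3) is slightly
larger than a monolithic training run would need.

The robustness benchmark checks an *ordering* — median accuracy with no
failures ≥ with 10% dropout ≥ with 10% poisoning — not absolute numbers;
on easily separable phantom features the three medians can saturate and
tie, which still satisfies the ordering.

## Ledger

An append-only SHA-256 hash chain with a fixed authority set (5 validator
ids): each block stores index, round, previous block hash, the payload
digest, validator id and timestamp, and hashes its own header.  The
canonical weight serialization — the UTF-8 registry string
`name:shape;...` followed by little-endian float64 bytes in registry
order — is fully specified so digests are reproducible across processes
and machines; an empty model hashes the empty byte string.  Verification
recomputes every hash and link in O(n); appending is O(1).  A
`fixed_clock` mode pins timestamps for golden-file tests.  This is the
proof-of-authority *essence* (only known validators may append; any
mutation is detectable) with no networking, consensus rounds, or
contracts.

## What the synthetic experiments do not show

Phantoms are radically simpler than clinical CT: no anatomy beyond one
ellipse, no partial-volume effects, no beam hardening or Hounsfield
calibration, a single slice geometry, and tumors that are always brighter
than brain tissue.  Perfect or near-perfect scores on phantoms demonstrate
that the machinery (training, selection, aggregation, auditing) works and
is reproducible — not that the architecture would reach comparable
accuracy on hospital data.  The pseudo-modality likewise exercises
alignment and leakage logic, not generative translation.  The
nearest-centroid evaluator inside the selection wrapper is a deliberate
substitution for a heavyweight inner classifier; rankings of feature
subsets may differ under a different evaluator.

## Numerical choices

Dice ε = 1e−6; batch-norm ε = 1e−5, momentum 0.9, eval mode uses running
statistics; squash guards `‖s‖ = 0` with a 1e−12 epsilon; MI clamps
negative rounding error at −1e−12; max-pool ties route gradients to the
first maximum; metrics with zero denominators are reported as explicit
nulls, never 0; both-empty masks have Dice = IoU = 1 by convention;
out-of-bounds optimizer proposals are clipped by default.
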