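# Methods

## Problem setting

`fedseg` simulates personalized federated learning (PFL) for binary
segmentation of 2-D grayscale medical images across K sites that cannot pool
their data. Each site k holds n_k image/mask pairs drawn from its own
distribution; both feature shift (scanner-like intensity differences) and
quantity skew (unequal n_k) are present. A central server coordinates T
communication rounds: broadcast of shared parameters, E epochs of local
training per client, and sample-count-weighted averaging

    omega_g^{t+1} = sum_k (n_k / N) * omega_k^t,      N = sum_k n_k,

over the shared parameter subset only.

## Model

The segmentation backbone is a classic U-Net: `depth` levels of double
3x3-conv blocks (conv → norm → ReLU, twice) with 2x2 max-pool downsampling, a
bridge (bottleneck) double-conv block, 2x2 transposed-conv upsampling with
skip concatenation, and a 1x1 convolution producing pre-sigmoid logits.
Sigmoid is applied only inside losses and metrics, for numerical stability.
The bridge output after its final activation is the latent representation
R(x); post-activation is the common choice in contrastive pipelines and the
alternative (pre-activation) is not exposed.

Normalization is selectable per config (`instance`, `batch`, `none`);
`instance` is the default because it behaves identically in training and
evaluation, carries no cross-site batch statistics, and is the variant that
avoids the aggregation-induced degradation that batch statistics suffer in
federated training. Batch norm is fully supported (running mean/variance
stored as non-trainable entries of the parameter set, biased variance,
momentum 0.1).

### Parameter partition

Each client's parameter set is split into a shared part (aggregated by the
server) and a personalized part (never transmitted). The split is static and
pattern-based: a parameter is personalized when its hierarchical name contains
any configured pattern as a substring or matches it as a glob. The default,
`["norm"]`, personalizes all normalization parameters (affine scale/shift and
any running statistics) — the closest concrete mechanism to keeping
site-specific feature statistics local. The partition is identical across
clients and constant over rounds; dynamic per-round parameter selection is out
of scope.

## Losses

Supervised loss per client (pixel probabilities ŷ = sigmoid(logits)):

    L_sup  = L_Dice + mu * L_BCE
    L_Dice = mean_i [ 1 − 2|y_i * ŷ_i| / (|y_i| + |ŷ_i| + eps) ]
    L_BCE  = mean_i mean_px [ −(y log ŷ + (1−y) log(1−ŷ)) ]

with mu = 1.0 by default and eps = 1e-6 in the Dice denominator only, so
nonempty cases are essentially exact while the doubly-empty 0/0 case evaluates
to loss 1 (a training-time convention; the evaluation Dice scores two empty
masks as 1). The BCE reference semantics clamp probabilities to
[eps, 1−eps]; the training graph evaluates the identical quantity in logit
space, mean(softplus(z) − z·y), which agrees with the clamped form to well
below 1e-5.

### Weighted model-contrastive regularizer

For every batch the client computes three site embeddings of the same inputs:
xi from the live local model, xi_g from a frozen snapshot of the received
global model, and xi_b from a frozen snapshot of the client's previous-round
model. With cosine similarity sim(a,b) = aᵀb/(‖a‖‖b‖) and temperature tau,

    L_con = −beta * log [ e^{sim(xi, xi_g)/tau}
                        / (e^{sim(xi, xi_g)/tau} + e^{sim(xi, xi_b)/tau}) ]
          =  beta * softplus((sim(xi, xi_b) − sim(xi, xi_g)) / tau),

the second form being the log-sum-exp-stable one actually computed. The
adaptive weight beta = exp(−n_k / N) strengthens the pull toward the global
model for data-poor clients; it uses training-split sizes, is computed once at
setup, and lies in (e^{−1}, 1]. Per batch the loss is the unweighted mean of
per-sample values. Zero-norm embeddings raise an error rather than silently
contributing zero similarity — dead bridge features should fail loudly.

The overall client objective is L = L_sup + alpha * L_con (alpha = 1.0
default; tau = 0.5 default, 0.1 being the preferable setting for the
lower-contrast CT-like task). Clients optimize with Adam(0.9, 0.999),
learning rate 1e-4 over 200 rounds in the reference recipe.

### Site embedding

F(·) maps R(x) (C channels) to a 2C-vector: channel-wise spatial average pool
concatenated with channel-wise spatial max pool, in that order. It adds no
learned parameters. Concatenation is the default fusion because it preserves
both statistics losslessly; element-wise sum (length C) is available via
`fusion="sum"`. Embeddings are not L2-normalized — cosine similarity
normalizes internally. The numpy-facing pooling sums values in sorted order,
making the average exactly independent of spatial memory layout; the training
graph uses the plain mean (its last-ulp order dependence is irrelevant under
a fixed execution order, and the gradient path must stay cheap).

## Round structure and snapshot semantics

- The positive snapshot merges the received global shared parameters over the
  client's own personalized parameters: the server never owns personalized
  layers, and reusing the client's is the minimal completion that makes
  R_{omega_g}(x) computable by a full network.
- Both snapshots are frozen for the whole round (no gradients, evaluation
  mode, no statistic updates).
- At t = 0 the previous-round cache is initialized to the initial global
  parameters. Then xi_g = xi_b for every sample, the contrastive term is the
  constant beta·ln 2, and its gradient cancels exactly — the first round is
  purely supervised. This is verified bitwise in the tests.
- All parameters (shared and personalized) are updated locally; after the E
  epochs the cache is refreshed with the new parameters.
- Participation is full (all K clients every round); clients are processed in
  ascending id, and every RNG stream (batch order, augmentation) is keyed by
  (seed, purpose, round, client), so client order cannot change results and a
  (config, seed) pair reproduces a run byte-for-byte.
- After the final aggregation the shared aggregate is broadcast once more, so
  each client ends holding its personalized model: final global shared parts
  plus its own personalized parts.

With alpha = 0 and an empty personalized pattern list the loop reduces exactly
to FedAvg; the test suite asserts trajectory equality against an independently
coded FedAvg reference over three rounds.

## Numerical backend

The environment provides no deep-learning framework, so the package carries a
small reverse-mode autodiff engine (`fedseg.nn`): float32 training tensors,
im2col convolutions in channels-last layout (contiguous GEMMs on CPU), fused
instance norm with the closed-form backward, 2x2 max-pool / transposed-conv
primitives, and Adam. Gradients of every primitive and of the full network are
validated against central finite differences in float64. One caveat for such
checks: zero-initialized biases can place pre-activations exactly on the ReLU
kink, where one-sided finite differences disagree with any valid subgradient;
the checks therefore randomize biases first.

## Synthetic multi-site data

The generator emulates the two non-IID axes of multi-center MRI/CT cohorts:

- **Feature shift.** Each site has its own foreground intensity, background
  offset, noise level, and a scanner-like power-law contrast nonlinearity
  (`contrast_gamma`). The nonlinearity matters: per-sample min-max
  normalization to [0, 1] (applied before training, as in the reference
  pipeline) removes affine differences, while a gamma difference moves the
  relative positions of background/foreground intensity clusters and therefore
  survives normalization. Pairwise Kolmogorov–Smirnov distances between
  post-normalization pixel marginals of the default fixtures exceed 0.1 (most
  pairs far more), so the non-IID claim is measurable, not assumed.
- **Quantity skew.** Packaged fixtures mirror published multi-site cohort
  sizes: `prostate_counts` (six sites, n_k = 421/384/468/175/261/158) and
  `cervical_counts` (eight sites, n_k = 255/219/197/129/41/43/76/73, total
  1033). `toy4` (60/50/30/20) is the desk-scale fixture.

Images contain one bright organ-like structure per image — a rotated ellipse
or a star-convex blob (ellipse radius modulated by 3rd/5th-order angular
harmonics) — on a noisy background; the mask is the shape support and is
nonempty by construction. Splits follow the 7 : 1.5 : 1.5 ratio with
floor(0.15·n) validation and test sizes and the remainder in training.
Training augmentation: rotation uniform in ±10° (bilinear image / nearest
mask, re-binarized), horizontal flip with probability 0.5, and an optional
random crop resized back.

What the generator does **not** emulate: anatomical texture and correlated
noise, multiple or absent foreground objects, annotation disagreement,
resolution/spacing heterogeneity, and production image sizes (fixtures default
to 64x64; the real pipelines use 384x384 / 256x256). Passing the desk-scale
tests therefore demonstrates the mechanics and the direction of the method's
effect under controlled heterogeneity, not clinical-grade performance.

## Desk-scale benchmark

`fedseg.evaluation.desk_benchmark` compares three methods under shared
initialization, data and data-order streams, per replicate seed:

- the personalized contrastive method (alpha = 1, tau = 0.5, norm layers
  personalized),
- FedAvg (alpha = 0, nothing personalized — the framework's own ablation),
- local-only training with the matched gradient-step budget
  (T·E·ceil(n_k/batch) steps per client).

Problem sizes were chosen to keep a full three-replicate comparison within a
desk-scale CPU budget: the toy4 fixture at 64x64, a depth-2 / width-8 U-Net,
batch 32, T = 20 rounds, E = 1. Because the reference recipe pairs lr = 1e-4
with 200 rounds, the 10x-shorter benchmark uses lr = 1e-3; the library default
remains 1e-4. Evaluation is the mean per-sample Dice of thresholded (0.5)
sigmoid predictions on each client's test split, averaged unweightedly across
clients. On this easy phantom task all methods sit near the performance
ceiling, so the expected signature is: all means well above 0.80, the
personalized method at or above FedAvg in most replicates, and a visible gain
over local-only on the smallest site (n_k = 20), where beta = e^{−n_k/N} is
largest. No published Dice value is claimed at this scale.

## Known limitations

- Static pattern-based partitioning only; no learned or per-round selection of
  shared parameters.
- Single-process simulation; determinism is prioritized over parallel speed.
- Binary segmentation with one output channel; no 3-D volumes or Transformer
  backbones.
- FedProx/FedBN/FedRep/MOON-style baselines are out of scope; FedAvg and
  local-only are the built-in comparators.
- The CPU autodiff backend is designed for desk-scale problems; wall-clock
  cost grows quickly with image size and width.
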