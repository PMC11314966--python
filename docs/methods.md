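# Methods

## The model

`protogan` clusters single-channel EEG/iEEG signals without labels by
learning, jointly, a generative model of their time-frequency images and
a set of latent *prototypes*, one per cluster.

The data space is the scalogram: each signal is bandpass-filtered
(0.5–40 Hz), cut into overlapping windows, transformed with a Morlet
continuous wavelet transform on a log-spaced frequency grid, rendered
through a colormap to a square 3-channel image, and scaled into the open
interval (−1, 1).

The latent space is a trainable mixture of N diagonal Gaussians,

    q(z) = Σ_k p(k) · N(z; μ_k, Σ_k),          z ∈ R^dz,  dz = 100.

Three DCGAN-style convolutional networks operate between the two spaces:
a generator G : z → image with a tanh output, a critic (discriminator)
D : image → R whose last-convolution activations double as a deep
feature map (DFM), and an encoder E : image → R^dz ending in global
average pooling. At the full configuration (64×64 images, width scale 1)
the critic flattens 4·4·512 = 8192 features; the published layer table
lists ReLU as the generator's output activation, which cannot produce
data in (−1, 1), so the output layer uses tanh — a deliberate deviation,
as is the absence of batch normalization in the critic (standard when a
gradient penalty regularizes it).

## Objectives

The critic minimizes the Wasserstein-GAN-with-gradient-penalty
objective

    L_D = −E[D(x_real)] + E[D(G(z))] + λ₁ E[(‖∇_x D(x̃)‖₂ − 1)²],

with x̃ drawn uniformly on segments between real and generated batches
(λ₁ = 10). The generator, encoder, and mixture parameters jointly
minimize

    L_total = (1/B) Σ_i [ −D(G(z_i)) + λ₂ · l_U2C(z_i) ],   λ₂ = 1,

where the unsupervised conditional contrastive (U2C) loss pulls the
encoding e_i = E(G(z_i)) toward the prototype of the component K_i that
(most likely) generated z_i, against the other in-batch prototypes:

    l_U2C(z_i) = −log [ exp(cos θ_ii) / ((1/B) Σ_j exp(cos θ_ij)) ],
    cos θ_ij = e_i · μ_{K_j} / (‖e_i‖ ‖μ_{K_j}‖).

K_i is the arg-max of the unnormalized log posterior
log N(z_i; μ_k, Σ_k) + log p(k), ties toward the smaller index.

## Training

D and (G, E, μ, Σ, p) alternate: b_D critic steps (default 5), then one
joint step. Networks use Adam with moment coefficients (0.5, 0.9) —
the usual WGAN-GP setting — at learning rates η = 10⁻⁴ for G and E and
4η for D. Latent parameters use plain SGD: 10γ for μ, γ for Σ and p,
with γ = 0.004. Batch size defaults to 64 and iterations to 18 000.

Latent-parameter gradients come from differentiating a per-step
surrogate: component draws are reparameterized (z = μ_K + Σ_K^{1/2} ε),
so μ and Σ receive pathwise gradients, including the direct dependence
of the U2C cosines on μ. For the mixing coefficients the mixture
decomposition E_q[f] = Σ_k p_k E_{z∼N_k}[f] gives the exact derivative
∂E/∂p_k = E_{N_k}[f], estimated by per-component batch means of the
per-sample losses (components absent from a batch contribute no relative
gradient). The generic `update_latent_parameters` operation applies one
SGD step against any differentiable objective of the mixture and then
restores validity — Euclidean projection of p onto the simplex with
floor ε_p = 10⁻⁴ and a positive floor ε_σ = 10⁻⁶ on covariance
diagonals; its gradients are validated against central finite
differences on a frozen toy.

Inside the training loop, p is stepped in logit space
(p = softmax(ρ), SGD on ρ at rate γ, then the ε_p floor): direct
projected steps at the published rate let the early, noisy
per-component critic differences collapse a component within ~100
iterations, while logit steps scale with p_k and are self-limiting, so
the mixture drifts toward the data proportions only as fast as the
evidence accumulates. Simplex membership and covariance positivity are
enforced after every step either way.

All randomness flows from a single integer seed per run. A run aborts
with a diagnostic after 50 consecutive non-finite losses, or
immediately if a latent objective evaluates non-finite.

## Clustering by compositive similarity

A trained model assigns a query scalogram x_query to a cluster by
comparing it with each cluster k on three levels:

* latent: cosine similarity between E(x_query) and μ_k;
* image: 1 / mean|x_query − G(μ_k)| (baselines G(μ_k) cached per model;
  the reciprocal is guarded at ε_d = 10⁻⁶, so an exact match scores
  10⁶);
* DFM: the same reciprocal comparison on the critic's last-convolution
  activations.

The L1 distances are means rather than sums, making scores independent
of image resolution; the subsequent normalization makes that choice
assignment-invariant. Each level's length-N vector is min–max
normalized across the N clusters (a constant vector maps to 0.5
everywhere), combined with weights α = (1/3, 1/3, 1/3) by default, and
converted to probabilities with SoftMax at temperature 1. The
assignment is the arg-max of the combined score, ties toward the
smaller cluster. Normalization is per query; no dataset-level state is
kept, so clustering is deterministic and order-independent. A grid
utility evaluates alternative weights on the simplex (default step
0.1); the ablation modes are (1,0,0), (1/2,1/2,0), (1/3,1/3,1/3).

## Evaluation

Purity, adjusted Rand index, and normalized mutual information are
computed from the class-vs-cluster contingency table. NMI uses natural
logarithms and the geometric-mean normalizer MI/√(H(C)H(K)).
Degenerate conventions: if both partitions are trivial the ARI is 1; if
either entropy is zero, NMI is 1 when the two partitions coincide as
set-partitions and 0 otherwise.

## Synthetic data

The fixture generator emulates three signal families styled after the
published descriptions: a fast (18–30 Hz) moderate-amplitude
"healthy-like" class (−180…100 μV), a slow (1–4 Hz) low-amplitude
"inter-ictal-like" class (−70…70 μV), and a transient-rich
"ictal-like" class (2–12 Hz, ±300 μV) carrying periodic
spike-and-slow-wave complexes (70 ms spike, ~350 ms slow wave, within
the printed 200–500 ms range). Each class member is a time-shifted copy
of a fixed three-tone template plus band-limited and white noise, so
classes are deliberately stereotyped — "trivially separable" in the
sense the desk-scale checks require (a nearest-class-mean classifier
reaches 100% on scalograms). Class imbalance is exact by
largest-remainder apportionment (e.g. 2:2:1 over 300 signals gives
120/120/60). The generator does not model amplitude nonstationarity,
artifacts, channel effects, or real epileptiform morphology beyond the
spectral/amplitude/transient caricature, so green desk-scale checks
demonstrate that the machinery works on separable data, not that it
reaches the published indexes on real recordings.

## Problem sizes and numerical choices

The full configuration (64×64, full width, B = 64, 18 000 iterations)
matches the published setup and is practical on a GPU-class budget. The
package's desk-scale configuration — used by the test suite and chosen
as a single-CPU working point — is 32×32 scalograms, eighth-width
networks, B = 16, b_D = 2, 1500 iterations, 300 signals; one training
run takes about three minutes on one CPU core. Networks compute in float32;
latent parameters and all similarity/metric computations in float64.
Scalogram rendering uses 64 log-spaced Morlet scales over 0.5–40 Hz,
magnitude (not power), the "jet" colormap, bilinear resampling, and
per-image scaling into (−1 + 10⁻³, 1 − 10⁻³); constant images map to
zeros. The FIR bandpass is a Hamming-windowed sinc of order
≈ 3.3·fs/2 Hz applied forward–backward (zero phase). The 2.88 s window
at 173.61 Hz rounds to exactly 500 samples, reproducing 15 segments per
4096-sample record.

## Known limitations

* The gradient-penalty and latent-update machinery rely on the
  package's own autodiff/conv layer; it is exact but not fast — full
  64×64 training at the published iteration count is a long single-CPU
  run.
* Clustering quality at desk scale depends on the synthetic classes
  being separable; overlapping-band classes (e.g. slow vs.
  spike-and-wave) are the first to merge when training is short.
* The mixing-coefficient dynamics are only as good as the per-component
  loss estimates; with very small batches (≲ 4 per component) p drifts
  slowly and may not reach the data proportions within short runs.
* EDF support covers standard 16-bit EDF with channel selection; EDF+
  annotations are ignored.
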