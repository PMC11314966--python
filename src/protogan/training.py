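"""Objectives and the alternating training loop.

The critic is trained with the WGAN-GP objective

    L_D = -E[D(x_real)] + E[D(G(z))] + lambda1 * E[(||grad_x D(x~)||_2 - 1)^2]

with ``x~`` sampled uniformly on segments between real and generated
images.  The generator, encoder, and the latent mixture parameters
minimize the total objective

    L_total = (1/B) sum_i ( -D(G(z_i)) + lambda2 * l_U2C(z_i) )

where the unsupervised conditional contrastive (U2C) loss pulls the
encoding of each generated sample toward the prototype of the mixture
component it was assigned to, against the other in-batch prototypes:

    l_U2C(z_i) = -log exp(cos th_ii) / ((1/B) sum_j exp(cos th_ij)),
    cos th_ij = e_i . mu_{K_j} / (||e_i|| ||mu_{K_j}||).

Latent parameters are updated by plain SGD on gradients obtained by
differentiating a (stochastic) objective of the mixture parameters:
means and covariances receive pathwise gradients through reparameterized
sampling, and the mixing coefficients receive the exact mixture-
decomposition derivative dE/dp_k = E_{z~N_k}[f] estimated per batch.
The training loop steps the mixing coefficients in logit space (self-
limiting near the simplex boundary); the standalone update operation
uses Euclidean simplex projection with a floor.  Covariance diagonals
are always floored at a positive minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .model import (
    EPS_P,
    EPS_SIGMA,
    GanBundle,
    LatentBatch,
    LatentGMM,
    assign_component,
    build_networks,
    save_checkpoint,
)

__all__ = [
    "TrainConfig",
    "LossReport",
    "gradient_penalty",
    "discriminator_loss",
    "adversarial_loss",
    "u2c_loss",
    "u2c_loss_per_sample",
    "total_objective",
    "latent_gradients",
    "update_latent_parameters",
    "project_simplex_with_floor",
    "train",
]


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``eta`` is the base network learning rate (the discriminator runs at
    ``4 * eta``), ``gamma`` the base latent rate (prototypes ``mu_k`` run
    at ``10 * gamma``), ``lambda1`` the gradient-penalty coefficient and
    ``lambda2`` the U2C weight.  ``b_D`` counts critic steps per joint
    generator/encoder/latent step.
    """

    eta: float = 1e-4
    gamma: float = 0.004
    lambda1: float = 10.0
    lambda2: float = 1.0
    B: int = 64
    b_D: int = 5
    iterations: int = 18000
    seed: int = 0
    adam_betas: tuple = (0.5, 0.9)

    def __post_init__(self):
        if min(self.eta, self.gamma) <= 0:
            raise ValueError("learning rates must be positive")
        if self.B < 2:
            raise ValueError("batch size must be >= 2 (U2C needs in-batch negatives)")
        if self.b_D < 1:
            raise ValueError("b_D must be >= 1")

    @property
    def lr_discriminator(self) -> float:
        return 4.0 * self.eta

    @property
    def lr_mu(self) -> float:
        return 10.0 * self.gamma

    @classmethod
    def from_file(cls, path) -> "TrainConfig":
        """Load from YAML or JSON with keys named as the fields above."""
        import json

        import yaml

        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if "adam_betas" in data:
            data["adam_betas"] = tuple(data["adam_betas"])
        return cls(**data)


@dataclass
class LossReport:
    """Per-logged-step loss trajectory plus the mixture weights."""

    steps: list = field(default_factory=list)
    d_loss: list = field(default_factory=list)
    adv_loss: list = field(default_factory=list)
    u2c_loss: list = field(default_factory=list)
    total_loss: list = field(default_factory=list)
    p: list = field(default_factory=list)

    def append(self, step, d, adv, u2c, total, p):
        self.steps.append(int(step))
        self.d_loss.append(float(d))
        self.adv_loss.append(float(adv))
        self.u2c_loss.append(float(u2c))
        self.total_loss.append(float(total))
        self.p.append(np.asarray(p, dtype=float).copy())

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "step": self.steps,
                "d_loss": self.d_loss,
                "adv": self.adv_loss,
                "u2c": self.u2c_loss,
                "total": self.total_loss,
            }
        )
        if self.p:
            for k in range(len(self.p[0])):
                df[f"p{k + 1}"] = [row[k] for row in self.p]
        return df

    def save_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# losses


def _critic_fn(critic):
    if isinstance(critic, GanBundle):
        return critic.D
    return critic


def gradient_penalty(critic, x_real, x_fake, lambda1: float = 10.0, seed=None):
    """WGAN-GP penalty ``lambda1 * E[(||grad_x D(x~)||_2 - 1)^2]``.

    ``x~`` interpolates each real/fake pair with an independent uniform
    weight.  ``critic`` may be a :class:`GanBundle` or any callable built
    from autodiff primitives.  Returns a scalar graph node.
    """
    D = _critic_fn(critic)
    xr = np.asarray(x_real if not isinstance(x_real, Tensor) else x_real.data)
    xf = np.asarray(x_fake if not isinstance(x_fake, Tensor) else x_fake.data)
    if xr.shape != xf.shape:
        raise ValueError(f"shape mismatch {xr.shape} vs {xf.shape}")
    if lambda1 < 0:
        raise ValueError("lambda1 must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=(xr.shape[0],) + (1,) * (xr.ndim - 1)).astype(xr.dtype)
    x_mix = Tensor(u * xr + (1.0 - u) * xf, requires_grad=True)
    score = D(x_mix).sum()
    (gx,) = ad.grad(score, [x_mix], create_graph=True)
    axes = tuple(range(1, xr.ndim))
    norms = ad.sqrt((gx * gx).sum(axis=axes) + 1e-12)
    return float(lambda1) * ((norms - 1.0) ** 2).mean()


def discriminator_loss(bundle: GanBundle, x_real, z_batch, lambda1: float = 10.0,
                       seed=None):
    """Critic objective: ``-E[D(x_real)] + E[D(G(z))] + gradient penalty``."""
    z = z_batch.z if isinstance(z_batch, LatentBatch) else np.asarray(z_batch)
    with ad.no_grad():
        x_fake = bundle.G(Tensor(np.asarray(z, dtype=nn.DTYPE))).data
    xr = np.asarray(x_real, dtype=nn.DTYPE)
    loss = -bundle.D(Tensor(xr)).mean() + bundle.D(Tensor(x_fake)).mean()
    if lambda1 > 0:
        loss = loss + gradient_penalty(bundle, xr, x_fake, lambda1, seed)
    return loss


def adversarial_loss(bundle: GanBundle, z_i):
    """Per-sample WGAN adversarial loss ``-D(G(z_i))``; returns (B,)."""
    z = np.atleast_2d(np.asarray(z_i, dtype=nn.DTYPE))
    return -bundle.D(bundle.G(Tensor(z)))


def _rows_unit(v):
    norms = ad.sqrt((v * v).sum(axis=1, keepdims=True))
    if np.any(norms.data < 1e-30):
        raise ValueError("zero-norm vector in cosine similarity")
    return v / norms


def u2c_loss_per_sample(e, assignments, gmm: LatentGMM):
    """Vector of per-sample U2C losses, shape (B,).

    ``assignments`` holds 1-based component ids ``K_i``; ``gmm.mu`` may be
    an autodiff tensor so prototype gradients flow.
    """
    e_t = e if isinstance(e, Tensor) else Tensor(np.atleast_2d(np.asarray(e, float)))
    ks = np.asarray(assignments, dtype=int) - 1
    mu = gmm.mu if isinstance(gmm.mu, Tensor) else Tensor(np.asarray(gmm.mu, float))
    if np.any(ks < 0) or np.any(ks >= mu.shape[0]):
        raise ValueError("assignment id out of range")
    B = e_t.shape[0]
    if ks.shape != (B,):
        raise ValueError("one assignment per encoded vector required")
    mu_sel = ad.take_rows(mu, ks)  # (B, dz): prototype of each j's component
    cos = ad.matmul(_rows_unit(e_t), _rows_unit(mu_sel).transpose((1, 0)))  # (B,B)
    eye = np.eye(B, dtype=cos.dtype)
    cos_ii = (cos * eye).sum(axis=1)
    return -cos_ii + ad.log(ad.exp(cos).mean(axis=1))


def u2c_loss(e, assignments, gmm: LatentGMM):
    """Batch-mean U2C loss (scalar graph node)."""
    return u2c_loss_per_sample(e, assignments, gmm).mean()


def total_objective(bundle: GanBundle, gmm: LatentGMM, z_batch, lambda2: float = 1.0):
    """Mean of adversarial plus ``lambda2``-weighted U2C terms.

    The per-sample pipeline is ``z -> G -> (D, E)`` with component
    assignments from the unnormalized posterior argmax.
    """
    z = z_batch.z if isinstance(z_batch, LatentBatch) else np.asarray(z_batch)
    z_t = z if isinstance(z, Tensor) else Tensor(np.atleast_2d(z))
    numeric = LatentGMM(
        np.asarray(gmm.p.data if isinstance(gmm.p, Tensor) else gmm.p),
        np.asarray(gmm.mu.data if isinstance(gmm.mu, Tensor) else gmm.mu),
        np.asarray(gmm.sigma.data if isinstance(gmm.sigma, Tensor) else gmm.sigma),
    )
    ks = assign_component(np.atleast_2d(np.asarray(z_t.data, dtype=float)), numeric)
    x_g = bundle.G(ad.cast(z_t, nn.DTYPE))
    ladv = -bundle.D(x_g)
    e = bundle.E(x_g)
    return (ladv + float(lambda2) * u2c_loss_per_sample(e, ks, gmm)).mean()


# ---------------------------------------------------------------------------
# latent-parameter updates


def project_simplex_with_floor(v: np.ndarray, floor: float = EPS_P) -> np.ndarray:
    """Euclidean projection onto ``{p : sum p = 1, p_k >= floor}``."""
    v = np.asarray(v, dtype=float)
    n = v.size
    scale = 1.0 - n * floor
    if scale <= 0:
        raise ValueError("floor too large for the number of components")
    w = (v - floor) / scale
    u = np.sort(w)[::-1]
    css = np.cumsum(u)
    idx = np.arange(1, n + 1)
    rho = np.nonzero(u - (css - 1.0) / idx > 0)[0][-1]
    theta = (css[rho] - 1.0) / (rho + 1.0)
    return np.maximum(w - theta, 0.0) * scale + floor


def latent_gradients(gmm: LatentGMM, objective):
    """Gradients of ``objective`` w.r.t. ``(p, mu, sigma)`` via autodiff.

    ``objective`` receives a mixture view whose fields are graph tensors
    and must return a scalar graph node.
    """
    p_t = Tensor(np.asarray(gmm.p, dtype=float), requires_grad=True)
    mu_t = Tensor(np.asarray(gmm.mu, dtype=float), requires_grad=True)
    sig_t = Tensor(np.asarray(gmm.sigma, dtype=float), requires_grad=True)
    value = objective(LatentGMM(p_t, mu_t, sig_t))
    if not np.isfinite(value.item()):
        raise RuntimeError(
            f"latent objective is non-finite ({value.item()}); aborting update"
        )
    grads = ad.grad(value, [p_t, mu_t, sig_t])
    out = []
    for g, ref in zip(grads, (p_t, mu_t, sig_t)):
        out.append(np.zeros_like(ref.data) if g is None else np.asarray(g.data, float))
    return value.item(), tuple(out)


def update_latent_parameters(gmm: LatentGMM, objective, gamma: float,
                             seed=None) -> LatentGMM:
    """One SGD step on the mixture parameters against ``objective``.

    Prototypes ``mu_k`` step at ``10 * gamma``; covariance diagonals and
    mixing coefficients step at ``gamma``.  Afterwards ``p`` is
    re-projected onto the floored simplex and covariance diagonals are
    floored at a positive minimum, so mixture invariants always hold.
    """
    _, (g_p, g_mu, g_sig) = latent_gradients(gmm, objective)
    mu = np.asarray(gmm.mu, dtype=float) - 10.0 * gamma * g_mu
    sigma = np.maximum(np.asarray(gmm.sigma, dtype=float) - gamma * g_sig, EPS_SIGMA)
    p = project_simplex_with_floor(np.asarray(gmm.p, dtype=float) - gamma * g_p)
    return LatentGMM(p=p, mu=mu, sigma=sigma).validate()


# ---------------------------------------------------------------------------
# training loop


def _stochastic_latent_objective(bundle, gmm_view, numeric_gmm, B, lambda2, rng):
    """Single-minibatch surrogate whose autodiff gradients estimate the
    latent-parameter gradients of the expected total objective.

    Component draws are reparameterized through ``mu``/``sigma``.  For the
    mixing coefficients the mixture decomposition
    ``E_q[f] = sum_k p_k E_{z~N_k}[f]`` gives the exact derivative
    ``dE/dp_k = E_{z~N_k}[f]``, estimated by the per-component batch means
    of the per-sample losses; a linear term carries it through autodiff
    (components absent from the batch get the batch mean, which the
    simplex projection treats as no information).
    """
    N, dz = numeric_gmm.n_components, numeric_gmm.dz
    ks = rng.choice(N, size=B, p=numeric_gmm.p)
    eps = rng.standard_normal((B, dz))
    z = ad.take_rows(gmm_view.mu, ks) + ad.sqrt(ad.take_rows(gmm_view.sigma, ks)) * eps
    x_g = bundle.G(ad.cast(z, nn.DTYPE))
    ladv = -bundle.D(x_g)
    e = bundle.E(x_g)
    assign = assign_component(z.data, numeric_gmm)
    u2c_vec = u2c_loss_per_sample(e, assign, gmm_view)
    f = ladv + lambda2 * u2c_vec
    f_data = np.asarray(f.data, dtype=float)
    comp_mean = np.full(N, f_data.mean())
    for k in range(N):
        sel = ks == k
        if sel.any():
            comp_mean[k] = f_data[sel].mean()
    p_term = (Tensor(comp_mean) * gmm_view.p).sum() - float(
        comp_mean @ numeric_gmm.p
    )
    parts = (float(np.mean(ladv.data)), float(np.mean(u2c_vec.data)))
    return f.mean() + p_term, f, parts


def train(
    dataset,
    cfg: TrainConfig,
    n_components: int = 3,
    image_size: int = 64,
    width_scale: float = 1.0,
    bundle: GanBundle | None = None,
    gmm: LatentGMM | None = None,
    log_every: int = 50,
    checkpoint_dir=None,
    checkpoint_every: int | None = None,
    progress: bool = False,
):
    """Alternating WGAN-GP / total-objective training.

    Each iteration runs ``cfg.b_D`` critic steps followed by one joint
    step of the generator, encoder, and latent mixture.  Networks use
    Adam; latent parameters use plain SGD at the per-parameter rates
    described in :class:`TrainConfig`.  Returns
    ``(bundle, gmm, LossReport)``.
    """
    data = _as_dataset_array(dataset, image_size)
    n = data.shape[0]
    if n < cfg.B:
        raise ValueError(f"dataset size {n} smaller than batch size {cfg.B}")
    rng = np.random.default_rng(cfg.seed)
    if bundle is None:
        bundle = build_networks(image_size, dz=100, width_scale=width_scale,
                                seed=int(rng.integers(2**31 - 1)))
    if gmm is None:
        gmm = LatentGMM(
            p=np.full(n_components, 1.0 / n_components),
            mu=rng.standard_normal((n_components, bundle.dz)),
            sigma=np.ones((n_components, bundle.dz)),
        ).validate()
    bundle.train()

    opt_D = nn.Adam(bundle.D.parameters(), cfg.lr_discriminator, cfg.adam_betas)
    opt_G = nn.Adam(bundle.G.parameters(), cfg.eta, cfg.adam_betas)
    opt_E = nn.Adam(bundle.E.parameters(), cfg.eta, cfg.adam_betas)
    # mixing coefficients are trained through logits: steps scale with p_k,
    # which keeps early (noisy) critic differences from collapsing a
    # component before the contrastive loss has specialized it
    rho = np.log(np.asarray(gmm.p, dtype=float))

    report = LossReport()
    bad_streak = 0
    iterator = range(cfg.iterations)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="train")
    for step in iterator:
        # -- critic steps ---------------------------------------------------
        d_val = np.nan
        for _ in range(cfg.b_D):
            idx = rng.choice(n, size=cfg.B, replace=n < cfg.B * 2)
            zb = _sample_batch(gmm, cfg.B, rng)
            d_loss_t = discriminator_loss(bundle, data[idx], zb, cfg.lambda1, rng)
            nn.backward(d_loss_t, bundle.D.parameters())
            opt_D.step()
            d_val = d_loss_t.item()

        # -- joint generator / encoder / latent step ------------------------
        p_t = Tensor(gmm.p, requires_grad=True)
        mu_t = Tensor(gmm.mu, requires_grad=True)
        sig_t = Tensor(gmm.sigma, requires_grad=True)
        view = LatentGMM(p_t, mu_t, sig_t)
        loss_t, f, (adv_val, u2c_val) = _stochastic_latent_objective(
            bundle, view, gmm, cfg.B, cfg.lambda2, rng
        )
        params = bundle.G.parameters() + bundle.E.parameters() + [p_t, mu_t, sig_t]
        nn.backward(loss_t, params)
        opt_G.step()
        opt_E.step()
        g_p = _grad_or_zero(p_t)
        g_rho = gmm.p * (g_p - float(gmm.p @ g_p))  # chain rule through softmax
        rho = rho - cfg.gamma * g_rho
        rho = rho - rho.max()
        p_soft = np.exp(rho)
        p_soft /= p_soft.sum()
        n_comp = p_soft.size
        gmm = LatentGMM(
            p=(1.0 - n_comp * EPS_P) * p_soft + EPS_P,
            mu=gmm.mu - cfg.lr_mu * _grad_or_zero(mu_t),
            sigma=np.maximum(gmm.sigma - cfg.gamma * _grad_or_zero(sig_t), EPS_SIGMA),
        ).validate()

        total_val = float(np.mean(f.data))
        if not np.isfinite(total_val) or not np.isfinite(d_val):
            bad_streak += 1
            if bad_streak >= 50:
                raise RuntimeError(
                    f"non-finite losses for {bad_streak} consecutive steps "
                    f"(last d_loss={d_val}, total={total_val})"
                )
        else:
            bad_streak = 0

        if step % log_every == 0 or step == cfg.iterations - 1:
            report.append(step, d_val, adv_val, u2c_val, total_val, gmm.p)
        if checkpoint_dir is not None and checkpoint_every and (
            (step + 1) % checkpoint_every == 0 or step == cfg.iterations - 1
        ):
            Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
            save_checkpoint(
                Path(checkpoint_dir) / f"checkpoint_{step + 1:06d}.npz", bundle, gmm
            )
    bundle.eval()
    return bundle, gmm, report


def _grad_or_zero(t: Tensor) -> np.ndarray:
    return np.zeros_like(t.data) if t.grad is None else np.asarray(t.grad, float)


def _sample_batch(gmm: LatentGMM, B: int, rng) -> LatentBatch:
    comp = rng.choice(gmm.n_components, size=B, p=gmm.p)
    z = gmm.mu[comp] + np.sqrt(gmm.sigma[comp]) * rng.standard_normal(
        (B, gmm.dz)
    )
    return LatentBatch(z=z, component=comp + 1)


def _as_dataset_array(dataset, image_size: int) -> np.ndarray:
    """Stack scalograms or accept a ready (n, s, s, 3) array."""
    if isinstance(dataset, np.ndarray):
        arr = dataset
    else:
        arr = np.stack([
            it.pixels if hasattr(it, "pixels") else np.asarray(it)
            for it in dataset
        ])
    arr = np.asarray(arr, dtype=nn.DTYPE)
    if arr.ndim != 4 or arr.shape[1:] != (image_size, image_size, 3):
        raise ValueError(
            f"expected (n, {image_size}, {image_size}, 3) data, got {arr.shape}"
        )
    return arr
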