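"""The Gaussian-mixture latent prior and the generator/discriminator/encoder.

The latent space is a trainable mixture of ``N`` diagonal Gaussians,
``q(z) = sum_k p(k) N(z; mu_k, Sigma_k)``; each mean vector ``mu_k`` acts
as the prototype of cluster ``k``.  The three networks follow the DCGAN
convolutional ladder: the generator upsamples a latent vector to a square
3-channel scalogram with a tanh output (so samples land in the data range
(-1, 1)), the discriminator mirrors it down to a scalar critic score and
exposes its last-convolution activations as a deep feature map (DFM), and
the encoder maps an image back to the latent dimension through global
average pooling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

__all__ = [
    "LatentGMM",
    "LatentBatch",
    "GanBundle",
    "init_latent_gmm",
    "sample_latent",
    "assign_component",
    "log_component_posteriors",
    "build_networks",
    "generate",
    "encode",
    "deep_feature_map",
    "save_checkpoint",
    "load_checkpoint",
]

#: floor on mixing coefficients, keeping every component alive
EPS_P = 1e-4
#: floor on diagonal covariance entries
EPS_SIGMA = 1e-6


@dataclass
class LatentGMM:
    """Trainable mixture prior: mixing weights, means, diagonal covariances.

    ``mu`` is (N, dz), ``sigma`` holds the positive diagonal of each
    covariance as (N, dz), ``p`` sums to one with every entry >= EPS_P.
    Fields may temporarily hold autodiff tensors during an update; use
    :meth:`validate` on the numeric state.
    """

    p: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray

    @property
    def n_components(self) -> int:
        return self.mu.shape[0]

    @property
    def dz(self) -> int:
        return self.mu.shape[1]

    def validate(self) -> "LatentGMM":
        p, mu, sigma = map(np.asarray, (self.p, self.mu, self.sigma))
        if mu.shape != sigma.shape or p.shape != (mu.shape[0],):
            raise ValueError("inconsistent mixture shapes")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixing coefficients sum to {p.sum()}, not 1")
        if np.any(p < EPS_P - 1e-12):
            raise ValueError("mixing coefficient below floor")
        if np.any(sigma <= 0):
            raise ValueError("covariance diagonal must be positive")
        return self

    def copy(self) -> "LatentGMM":
        return LatentGMM(self.p.copy(), self.mu.copy(), self.sigma.copy())


@dataclass
class LatentBatch:
    """Latent vectors plus the 1-based id of the component that drew each."""

    z: np.ndarray
    component: np.ndarray


def init_latent_gmm(N: int, dz: int = 100, seed: int = 0) -> LatentGMM:
    """Uniform weights, identity covariances, standard-normal means."""
    if N < 2:
        raise ValueError("clustering needs at least 2 mixture components")
    if dz < 1:
        raise ValueError("latent dimension must be >= 1")
    rng = np.random.default_rng(seed)
    return LatentGMM(
        p=np.full(N, 1.0 / N),
        mu=rng.standard_normal((N, dz)),
        sigma=np.ones((N, dz)),
    ).validate()


def sample_latent(gmm: LatentGMM, B: int, seed=None) -> LatentBatch:
    """Draw ``B`` vectors from the mixture; ``seed`` may be an int or rng."""
    if B < 1:
        raise ValueError("batch size must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    comp = rng.choice(gmm.n_components, size=B, p=np.asarray(gmm.p, dtype=float))
    eps = rng.standard_normal((B, gmm.dz))
    z = gmm.mu[comp] + np.sqrt(gmm.sigma[comp]) * eps
    return LatentBatch(z=z, component=comp + 1)


def log_component_posteriors(z: np.ndarray, gmm: LatentGMM) -> np.ndarray:
    """Unnormalized log posterior log q(z|k) + log p(k), shape (B, N)."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    diff = z[:, None, :] - gmm.mu[None, :, :]  # (B, N, dz)
    quad = np.sum(diff * diff / gmm.sigma[None, :, :], axis=2)
    logdet = np.sum(np.log(gmm.sigma), axis=1)
    return (
        -0.5 * (quad + logdet[None, :] + gmm.dz * np.log(2 * np.pi))
        + np.log(gmm.p)[None, :]
    )


def assign_component(z: np.ndarray, gmm: LatentGMM):
    """Most likely generating component, ``argmax_k q(z|k) p(k)``, 1-based.

    Evaluated in the log domain; ties break toward the smaller index.
    Accepts a single vector or a batch.
    """
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    ids = np.argmax(log_component_posteriors(z, gmm), axis=1) + 1
    return int(ids[0]) if single else ids


# ---------------------------------------------------------------------------
# networks


@dataclass
class GanBundle:
    """Generator, discriminator, and encoder with their build geometry."""

    G: nn.Module
    D: nn.Module
    E: nn.Module
    image_size: int
    dz: int
    width_scale: float = 1.0

    def eval(self) -> "GanBundle":
        self.G.eval(), self.D.eval(), self.E.eval()
        return self

    def train(self) -> "GanBundle":
        self.G.train(), self.D.train(), self.E.train()
        return self


class _Generator(nn.Module):
    def __init__(self, image_size, dz, channels, rng):
        super().__init__()
        c0 = channels[0]
        self.fc = nn.Dense(dz, c0 * 4 * 4, rng)
        self.c0 = c0
        self.bn0 = nn.BatchNorm2d(c0)
        self.ups, self.bns = [], []
        for c_in, c_out in zip(channels[:-1], channels[1:]):
            self.ups.append(nn.ConvTranspose2d(c_in, c_out, rng))
            self.bns.append(nn.BatchNorm2d(c_out))
        self.out = nn.ConvTranspose2d(channels[-1], 3, rng)

    def forward(self, z):
        x = self.fc(z).reshape((-1, 4, 4, self.c0))
        x = ad.relu(self.bn0(x))
        for up, bn in zip(self.ups, self.bns):
            x = ad.relu(bn(up(x)))
        return ad.tanh(self.out(x))


class _Discriminator(nn.Module):
    """Critic; ``forward_features`` taps the last-convolution activations."""

    def __init__(self, image_size, channels, rng):
        super().__init__()
        self.convs = []
        c_prev = 3
        for c in channels:
            self.convs.append(nn.Conv2d(c_prev, c, rng))
            c_prev = c
        self.fc = nn.Dense(channels[-1] * 4 * 4, 1, rng)

    def forward_features(self, x):
        for conv in self.convs:
            x = ad.leaky_relu(conv(x), 0.2)
        return x.reshape((x.shape[0], -1))

    def forward(self, x):
        return self.fc(self.forward_features(x)).reshape((-1,))


class _Encoder(nn.Module):
    def __init__(self, image_size, dz, channels, rng):
        super().__init__()
        self.convs, self.bns = [], []
        c_prev = 3
        for c in channels:
            self.convs.append(nn.Conv2d(c_prev, c, rng))
            self.bns.append(nn.BatchNorm2d(c))
            c_prev = c
        self.fc = nn.Dense(channels[-1], dz, rng)

    def forward(self, x):
        for conv, bn in zip(self.convs, self.bns):
            x = ad.relu(bn(conv(x)))
        return self.fc(x.mean(axis=(1, 2)))


def _ladder_channels(image_size: int, width_scale: float):
    n_steps = int(np.log2(image_size // 4))
    if image_size not in (16, 32, 64) or 2 ** n_steps * 4 != image_size:
        raise ValueError(f"unsupported image size {image_size}; use 16/32/64")
    down = [max(4, int(round(64 * width_scale)) * 2**i) for i in range(n_steps)]
    return down  # discriminator/encoder order (shallow -> deep)


def build_networks(
    image_size: int = 64,
    dz: int = 100,
    width_scale: float = 1.0,
    seed: int = 0,
) -> GanBundle:
    """Build the three networks of the DCGAN ladder.

    At ``image_size=64`` and ``width_scale=1`` the discriminator runs
    3x64x64 -> 64 -> 128 -> 256 -> 512 feature maps with a flattened width
    of 8192, the generator mirrors it upward from a dense 100 -> 8192
    projection, and the encoder ends in global average pooling plus a
    dense layer onto ``dz``.  ``width_scale`` shrinks every channel count
    proportionally for desk-scale runs.
    """
    down = _ladder_channels(image_size, width_scale)
    rng = np.random.default_rng(seed)
    G = _Generator(image_size, dz, list(reversed(down)), rng)
    D = _Discriminator(image_size, down, rng)
    E = _Encoder(image_size, dz, down, rng)
    return GanBundle(G=G, D=D, E=E, image_size=image_size, dz=dz,
                     width_scale=width_scale)


def _as_image_batch(x, image_size: int) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=nn.DTYPE))
    if t.ndim == 3:
        t = t.reshape((1,) + t.shape)
    if t.shape[1:] != (image_size, image_size, 3):
        raise ValueError(
            f"expected (B, {image_size}, {image_size}, 3) images, got {t.shape}"
        )
    return t


def generate(bundle: GanBundle, z) -> np.ndarray:
    """Decode latent vectors to scalogram images in (-1, 1), order preserved."""
    z = np.atleast_2d(np.asarray(z, dtype=nn.DTYPE))
    if z.shape[1] != bundle.dz:
        raise ValueError(f"latent dimension {z.shape[1]} != {bundle.dz}")
    bundle.G.eval()
    with ad.no_grad():
        return bundle.G(Tensor(z)).data


def encode(bundle: GanBundle, x) -> np.ndarray:
    """Map images to dz-dimensional encoded vectors (inference mode)."""
    t = _as_image_batch(x, bundle.image_size)
    bundle.E.eval()
    with ad.no_grad():
        return bundle.E(t).data


def deep_feature_map(bundle: GanBundle, x) -> np.ndarray:
    """Flattened last-convolution discriminator activations per image."""
    t = _as_image_batch(x, bundle.image_size)
    with ad.no_grad():
        return bundle.D.forward_features(t).data


# ---------------------------------------------------------------------------
# checkpoints


CHECKPOINT_FORMAT_VERSION = 1


def save_checkpoint(path, bundle: GanBundle, gmm: LatentGMM) -> None:
    """Single-archive snapshot of all three networks plus the mixture."""
    arrays = {}
    for tag, net in (("G", bundle.G), ("D", bundle.D), ("E", bundle.E)):
        for name, arr in net.state_arrays().items():
            arrays[f"{tag}.{name}"] = arr
    arrays["gmm.p"] = np.asarray(gmm.p)
    arrays["gmm.mu"] = np.asarray(gmm.mu)
    arrays["gmm.sigma"] = np.asarray(gmm.sigma)
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "image_size": bundle.image_size,
        "dz": bundle.dz,
        "width_scale": bundle.width_scale,
        "n_components": gmm.n_components,
    }
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path, seed: int = 0):
    """Rebuild a (bundle, gmm) pair saved by :func:`save_checkpoint`."""
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"unsupported checkpoint format {meta['format_version']}"
            )
        arrays = {k: archive[k] for k in archive.files if k != "__meta__"}
    bundle = build_networks(
        image_size=int(meta["image_size"]),
        dz=int(meta["dz"]),
        width_scale=float(meta["width_scale"]),
        seed=seed,
    )
    for tag, net in (("G", bundle.G), ("D", bundle.D), ("E", bundle.E)):
        state = {
            k[len(tag) + 1 :]: v for k, v in arrays.items() if k.startswith(tag + ".")
        }
        net.load_state_arrays(state)
    gmm = LatentGMM(arrays["gmm.p"], arrays["gmm.mu"], arrays["gmm.sigma"]).validate()
    return bundle, gmm
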