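"""Latent-prototype compositive similarity clustering.

A trained model assigns a cluster to a query scalogram by comparing it
with each cluster's prototype on three levels:

* latent: cosine similarity between the encoded query ``E(x_query)`` and
  the prototype mean ``mu_k``;
* image: reciprocal mean absolute difference between the query and the
  cluster's baseline scalogram ``G(mu_k)``;
* deep feature map (DFM): the same reciprocal-L1 comparison on the
  discriminator's last-convolution activations.

Each level's length-N score vector is min-max normalized across the N
clusters, combined with weights ``(alpha1, alpha2, alpha3)`` summing to
one, converted to probabilities with SoftMax, and the cluster with the
highest combined score wins (ties toward the smaller index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GanBundle, LatentGMM, deep_feature_map, encode, generate

__all__ = [
    "SimilarityWeights",
    "ClusterResult",
    "BaselineCache",
    "latent_similarity",
    "image_similarity",
    "dfm_similarity",
    "compositive_similarity",
    "cluster_dataset",
    "weight_grid",
]

#: guard for the reciprocal-L1 similarities
EPS_D = 1e-6


@dataclass(frozen=True)
class SimilarityWeights:
    """Nonnegative level weights summing to one."""

    alpha1: float = 1.0 / 3.0
    alpha2: float = 1.0 / 3.0
    alpha3: float = 1.0 / 3.0

    def __post_init__(self):
        if min(self.alpha1, self.alpha2, self.alpha3) < 0:
            raise ValueError("similarity weights must be nonnegative")
        if abs(self.alpha1 + self.alpha2 + self.alpha3 - 1.0) > 1e-9:
            raise ValueError("similarity weights must sum to 1")

    LATENT_ONLY = None  # filled in below
    LATENT_IMAGE = None


SimilarityWeights.LATENT_ONLY = SimilarityWeights(1.0, 0.0, 0.0)
SimilarityWeights.LATENT_IMAGE = SimilarityWeights(0.5, 0.5, 0.0)


@dataclass
class ClusterResult:
    """Per-query raw scores, combined score, probabilities, assignment."""

    s_latent: np.ndarray
    s_image: np.ndarray
    s_dfm: np.ndarray
    s_com: np.ndarray
    prob: np.ndarray
    assignment: int  # 1-based cluster id


class BaselineCache:
    """Per-model cache of baseline scalograms ``G(mu_k)`` and their DFMs."""

    def __init__(self, bundle: GanBundle, gmm: LatentGMM):
        self.bundle = bundle
        self.gmm = gmm
        self.images = generate(bundle, np.asarray(gmm.mu))
        self.dfms = deep_feature_map(bundle, self.images)


def latent_similarity(e_query, gmm: LatentGMM) -> np.ndarray:
    """Cosine similarity of the encoded query against every prototype."""
    e = np.asarray(e_query, dtype=float).reshape(-1)
    mu = np.asarray(gmm.mu, dtype=float)
    ne = np.linalg.norm(e)
    nm = np.linalg.norm(mu, axis=1)
    if ne < 1e-30 or np.any(nm < 1e-30):
        raise ValueError("zero-norm vector in latent similarity")
    return mu @ e / (ne * nm)


def _reciprocal_l1(query: np.ndarray, baselines: np.ndarray) -> np.ndarray:
    diffs = np.mean(
        np.abs(baselines - query[None]), axis=tuple(range(1, baselines.ndim))
    )
    return 1.0 / np.maximum(diffs, EPS_D)


def _query_pixels(x_query, image_size: int) -> np.ndarray:
    pix = x_query.pixels if hasattr(x_query, "pixels") else np.asarray(x_query)
    if pix.shape != (image_size, image_size, 3):
        raise ValueError(f"query image has shape {pix.shape}")
    return np.asarray(pix, dtype=float)


def image_similarity(x_query, bundle: GanBundle, gmm: LatentGMM,
                     cache: BaselineCache | None = None) -> np.ndarray:
    """Reciprocal mean-|difference| against each baseline scalogram."""
    cache = cache or BaselineCache(bundle, gmm)
    q = _query_pixels(x_query, bundle.image_size)
    return _reciprocal_l1(q, np.asarray(cache.images, dtype=float))


def dfm_similarity(x_query, bundle: GanBundle, gmm: LatentGMM,
                   cache: BaselineCache | None = None) -> np.ndarray:
    """Reciprocal mean-|difference| on deep feature maps."""
    cache = cache or BaselineCache(bundle, gmm)
    q = _query_pixels(x_query, bundle.image_size)
    dfm_q = deep_feature_map(bundle, q[None]).reshape(-1)
    return _reciprocal_l1(dfm_q, np.asarray(cache.dfms, dtype=float))


def _minmax_norm(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi - lo == 0:
        return np.full_like(v, 0.5)
    return (v - lo) / (hi - lo)


def _softmax(s: np.ndarray) -> np.ndarray:
    e = np.exp(s - s.max())
    return e / e.sum()


def compositive_similarity(
    x_query,
    bundle: GanBundle,
    gmm: LatentGMM,
    w: SimilarityWeights = SimilarityWeights(),
    cache: BaselineCache | None = None,
) -> ClusterResult:
    """Three-level scoring, combination, SoftMax probabilities, assignment."""
    cache = cache or BaselineCache(bundle, gmm)
    q = _query_pixels(x_query, bundle.image_size)
    e_query = encode(bundle, q[None]).reshape(-1)
    s_latent = latent_similarity(e_query, gmm)
    s_image = image_similarity(q, bundle, gmm, cache)
    s_dfm = dfm_similarity(q, bundle, gmm, cache)
    s_com = (
        w.alpha1 * _minmax_norm(s_latent)
        + w.alpha2 * _minmax_norm(s_image)
        + w.alpha3 * _minmax_norm(s_dfm)
    )
    return ClusterResult(
        s_latent=s_latent,
        s_image=s_image,
        s_dfm=s_dfm,
        s_com=s_com,
        prob=_softmax(s_com),
        assignment=int(np.argmax(s_com)) + 1,
    )


def cluster_dataset(
    scalograms,
    bundle: GanBundle,
    gmm: LatentGMM,
    w: SimilarityWeights = SimilarityWeights(),
):
    """Cluster a collection; returns (assignments, probability table, results).

    ``assignments`` is an (n,) array of 1-based cluster ids and the
    probability table is (n, N).  Deterministic given the trained model.
    """
    items = list(scalograms)
    if not items:
        raise ValueError("empty query collection")
    cache = BaselineCache(bundle, gmm)
    results = [compositive_similarity(x, bundle, gmm, w, cache) for x in items]
    assignments = np.array([r.assignment for r in results], dtype=int)
    probs = np.stack([r.prob for r in results])
    return assignments, probs, results


def weight_grid(step: float = 0.1):
    """Grid over the weight simplex for sensitivity sweeps."""
    ticks = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    out = []
    for a1 in ticks:
        for a2 in ticks:
            a3 = 1.0 - a1 - a2
            if a3 >= -1e-9:
                out.append(SimilarityWeights(float(a1), float(a2),
                                             float(max(a3, 0.0))))
    return out
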