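"""External clustering indexes: Purity, ARI, NMI.

All three are computed from the class-vs-cluster contingency table
``n_ij`` (items in cluster ``v_i`` and class ``u_j``):

* Purity = (1/n) sum_i max_j n_ij;
* ARI    = pair-counting agreement corrected for chance;
* NMI    = MI(C, K) / sqrt(H(C) * H(K)) with natural-log entropies.

Degenerate conventions (the indexes are otherwise undefined): when both
partitions are trivial the ARI's denominator vanishes and 1 is returned;
when either partition has zero entropy, NMI is 1 if the two partitions
are identical as set-partitions and 0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContingencyTable",
    "contingency",
    "purity",
    "ari",
    "nmi",
    "evaluation_report",
]


@dataclass
class ContingencyTable:
    """Counts ``n_ij`` with clusters on rows and classes on columns."""

    n_ij: np.ndarray
    cluster_values: np.ndarray
    class_values: np.ndarray

    def __post_init__(self):
        self.n_ij = np.asarray(self.n_ij, dtype=np.int64)
        if self.n_ij.ndim != 2 or np.any(self.n_ij < 0):
            raise ValueError("contingency table must be a 2-D nonnegative array")

    @property
    def a(self) -> np.ndarray:
        """Cluster totals (row sums)."""
        return self.n_ij.sum(axis=1)

    @property
    def b(self) -> np.ndarray:
        """Class totals (column sums)."""
        return self.n_ij.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.n_ij.sum())


def contingency(class_labels, cluster_labels) -> ContingencyTable:
    """Cross-tabulate class labels against cluster labels.

    Label sets are discovered from the data (any hashable values).
    """
    class_labels = list(class_labels)
    cluster_labels = list(cluster_labels)
    if len(class_labels) != len(cluster_labels):
        raise ValueError(
            f"length mismatch: {len(class_labels)} classes vs "
            f"{len(cluster_labels)} clusters"
        )
    if not class_labels:
        raise ValueError("need at least one item")
    classes = sorted(set(class_labels), key=str)
    clusters = sorted(set(cluster_labels), key=str)
    ci = {c: i for i, c in enumerate(classes)}
    ki = {k: i for i, k in enumerate(clusters)}
    table = np.zeros((len(clusters), len(classes)), dtype=np.int64)
    for cls, clu in zip(class_labels, cluster_labels):
        table[ki[clu], ci[cls]] += 1
    return ContingencyTable(table, np.array(clusters), np.array(classes))


def purity(t: ContingencyTable) -> float:
    """Fraction of items in their cluster's majority class; in [0, 1]."""
    return float(t.n_ij.max(axis=1).sum() / t.n)


def _comb2(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x * (x - 1.0) / 2.0


def ari(t: ContingencyTable) -> float:
    """Adjusted Rand index from pair counts; 1 for identical partitions."""
    if t.n < 2:
        raise ValueError("ARI needs at least 2 items")
    sum_ij = _comb2(t.n_ij).sum()
    sum_a = _comb2(t.a).sum()
    sum_b = _comb2(t.b).sum()
    expected = sum_a * sum_b / _comb2(t.n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index - expected == 0:
        return 1.0  # both partitions trivial
    return float((sum_ij - expected) / (max_index - expected))


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def nmi(t: ContingencyTable) -> float:
    """Normalized mutual information with the geometric-mean normalizer."""
    n = t.n
    h_k = _entropy(t.a, n)
    h_c = _entropy(t.b, n)
    if h_k == 0.0 or h_c == 0.0:
        # a trivial partition: 1 iff the two partitions coincide, i.e. the
        # table is a one-to-one matching of clusters and classes
        nz = t.n_ij > 0
        identical = nz.sum(axis=0).max() == 1 and nz.sum(axis=1).max() == 1
        return 1.0 if identical else 0.0
    mask = t.n_ij > 0
    nij = t.n_ij[mask].astype(float)
    outer = np.outer(t.a, t.b)[mask].astype(float)
    mi = float((nij / n * np.log(nij * n / outer)).sum())
    return mi / np.sqrt(h_k * h_c)


def evaluation_report(rows, path=None):
    """Tabulate Purity/ARI/NMI rows and append mean +/- sd.

    ``rows`` is an iterable of dicts with keys ``group``/``seed`` plus the
    three indexes; returns a pandas DataFrame (written as CSV when
    ``path`` is given).
    """
    import pandas as pd

    df = pd.DataFrame(list(rows))
    summary = {}
    for col in ("purity", "ari", "nmi"):
        if col in df:
            summary[col] = f"{df[col].mean():.4f} +/- {df[col].std(ddof=1):.4f}"
    if path is not None:
        df.to_csv(path, index=False)
    return df, summary
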