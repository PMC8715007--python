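"""Alpha diversity, beta diversity and principal coordinates analysis.

Alpha indices: bias-corrected Chao1, Shannon entropy in nats, Gini–Simpson,
and Shannon evenness H / ln(S_obs). Beta: Bray–Curtis and unweighted UniFrac.
Ordination: classical (Torgerson) scaling; negative eigenvalues are reported
but contribute no axes, and proportion explained is taken over the positive
eigenvalues only.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from skbio import TreeNode
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import shannon as _skbio_shannon
from skbio.diversity.alpha import simpson as _skbio_simpson
from skbio.diversity.beta import unweighted_unifrac as _skbio_unweighted_unifrac

from .io import AbundanceTable


def alpha_diversity(counts) -> dict[str, float]:
    """Alpha-diversity indices of one sample's count vector.

    Chao1 = S_obs + F1(F1-1) / (2 (F2+1)) (bias-corrected); Shannon H in nats;
    Gini–Simpson 1 - Σ p_i²; evenness H / ln S_obs (0 when S_obs ≤ 1).
    """
    x = np.asarray(counts)
    if x.ndim != 1:
        raise ValueError("expected a single sample's count vector")
    if (x < 0).any():
        raise ValueError("negative counts")
    if x.sum() == 0:
        raise ValueError("all-zero count vector has no diversity")
    x = x[x > 0]
    s_obs = int(x.size)
    h = float(_skbio_shannon(x, base=math.e))
    return {
        "observed": s_obs,
        "chao1": float(_skbio_chao1(x, bias_corrected=True)),
        "shannon": h,
        "simpson": float(_skbio_simpson(x)),
        "evenness": h / math.log(s_obs) if s_obs > 1 else 0.0,
    }


def alpha_diversity_table(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample alpha indices for a whole count table."""
    rows = {s: alpha_diversity(table.counts.loc[s].values) for s in table.samples}
    return pd.DataFrame.from_dict(rows, orient="index")[
        ["observed", "chao1", "shannon", "simpson", "evenness"]
    ]


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity 1 - 2 Σ min(x_i, y_i) / (Σx + Σy)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative entries")
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("each vector needs a positive sum")
    return float(_scipy_braycurtis(x, y))


def unweighted_unifrac(presence_x, presence_y, tree: TreeNode, taxa: list[str]) -> float:
    """Unweighted UniFrac: unique observed branch length / total observed.

    ``presence_x``/``presence_y`` are count or presence vectors aligned to
    ``taxa``; every taxon with a positive entry must be a tip of ``tree``.
    """
    x = np.asarray(presence_x)
    y = np.asarray(presence_y)
    if x.shape != y.shape or len(taxa) != x.size:
        raise ValueError("presence vectors and taxa list must align")
    tips = {t.name for t in tree.tips()}
    observed = {t for t, xi, yi in zip(taxa, x, y) if xi > 0 or yi > 0}
    missing = sorted(observed - tips)
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    return float(_skbio_unweighted_unifrac(x, y, taxa=taxa, tree=tree))


def distance_matrix(table: AbundanceTable, metric: str = "braycurtis",
                    tree: TreeNode | None = None) -> pd.DataFrame:
    """All-pairs sample distance matrix (braycurtis or unweighted_unifrac)."""
    samples = table.samples
    n = len(samples)
    d = np.zeros((n, n))
    counts = table.counts.values
    taxa = table.taxa
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "braycurtis":
                d[i, j] = bray_curtis(counts[i], counts[j])
            elif metric == "unweighted_unifrac":
                if tree is None:
                    raise ValueError("unweighted_unifrac requires a tree")
                d[i, j] = unweighted_unifrac(counts[i], counts[j], tree, taxa)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            d[j, i] = d[i, j]
    return pd.DataFrame(d, index=samples, columns=samples)


@dataclasses.dataclass
class OrdinationResult:
    """Classical-scaling embedding: coordinates, eigenvalues, proportions."""

    coordinates: pd.DataFrame  # samples × axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives retained)
    proportion_explained: np.ndarray  # over positive eigenvalues, per reported axis


def pcoa(d: pd.DataFrame | np.ndarray, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis by classical (Torgerson) scaling.

    Double-centres -d²/2, eigendecomposes, and scales eigenvectors by the
    square root of the positive eigenvalues. Axes for non-positive eigenvalues
    are not returned; the eigenvalues themselves are.
    """
    if isinstance(d, pd.DataFrame):
        ids = list(d.index)
        m = d.values.astype(float)
    else:
        m = np.asarray(d, dtype=float)
        ids = [f"s{i}" for i in range(m.shape[0])]
    if m.shape[0] != m.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(m), 0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = m.shape[0]
    if n_axes is None:
        n_axes = n - 1
    if n_axes > n - 1:
        raise ValueError("n_axes must be <= n_samples - 1")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (m**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    positive = eigvals > tol
    k = min(n_axes, int(positive.sum()))
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k]) if k else np.zeros((n, 0))
    pos_sum = eigvals[positive].sum()
    proportions = (eigvals[:k] / pos_sum) if pos_sum > 0 else np.zeros(k)
    frame = pd.DataFrame(coords, index=ids, columns=[f"PCo{i + 1}" for i in range(k)])
    return OrdinationResult(frame, eigvals, proportions)
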