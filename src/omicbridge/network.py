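"""Ensemble co-occurrence network inference over taxa.

The procedure follows the classic ensemble recipe for compositional microbiome
data: score all taxon pairs with four association measures (Pearson, Spearman,
Bray–Curtis, symmetrized Kullback–Leibler), keep the top and bottom candidate
edges per measure, assess each candidate with a permutation null (optionally
re-closing samples to proportions after every shuffle, which absorbs the
spurious negative correlations closure induces) plus a bootstrap stability
interval, correct per measure with Benjamini–Hochberg, and keep edges
supported by at least ``min_support`` measures with a consistent sign,
reporting a Fisher-combined p.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

MEASURES = ("pearson", "spearman", "bray", "kld")
CORRELATION_MEASURES = frozenset({"pearson", "spearman"})
KLD_PSEUDOCOUNT = 1e-6


@dataclasses.dataclass
class Edge:
    source: str
    target: str
    source_type: str
    target_type: str
    measure: str
    score: float
    sign: int  # +1 copresence, -1 exclusion
    p: float
    q: float = float("nan")
    boot_low: float = float("nan")
    boot_high: float = float("nan")
    unstable: bool = False
    support: int = 1

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.source, self.target)))


@dataclasses.dataclass
class Candidate:
    i: int
    j: int
    measure: str
    score: float
    sign: int


# ---------------------------------------------------------------------------
# vectorized measure kernels; all operate along the last axis


def _pearson_nd(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    num = (xc * yc).sum(axis=-1)
    den = np.sqrt((xc**2).sum(axis=-1) * (yc**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _rank_nd(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=-1)


def _spearman_nd(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return _pearson_nd(_rank_nd(x), _rank_nd(y))


def _close_nd(a: np.ndarray) -> np.ndarray:
    s = a.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(s > 0, a / s, np.nan)


def _bray_nd(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bray–Curtis on cross-sample profiles each closed to sum 1."""
    p = _close_nd(x)
    q = _close_nd(y)
    return 1.0 - np.minimum(p, q).sum(axis=-1)


def _kld_nd(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Symmetrized KL divergence with pseudocount, profiles closed to sum 1."""
    p = _close_nd(_close_nd(x) + KLD_PSEUDOCOUNT)
    q = _close_nd(_close_nd(y) + KLD_PSEUDOCOUNT)
    return 0.5 * ((p - q) * np.log(p / q)).sum(axis=-1)


_KERNELS = {
    "pearson": _pearson_nd,
    "spearman": _spearman_nd,
    "bray": _bray_nd,
    "kld": _kld_nd,
}


def score_pair(x, y, measure: str) -> float:
    """Association score of two feature profiles under one measure."""
    if measure not in _KERNELS:
        raise ValueError(f"unknown measure {measure!r}")
    return float(_KERNELS[measure](np.asarray(x, float), np.asarray(y, float)))


def pairwise_scores(profiles: np.ndarray, measure: str) -> np.ndarray:
    """All-pairs score matrix over feature rows of ``profiles``.

    ``profiles`` is features × samples, columns already closed to proportions
    per sample. Correlation measures return NaN for constant profiles (the
    pair is skipped downstream); dissimilarity measures close each feature's
    cross-sample profile to sum 1 first.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    if measure == "pearson":
        with np.errstate(invalid="ignore"):
            m = np.corrcoef(profiles)
        sd = profiles.std(axis=1)
        m[sd == 0, :] = np.nan
        m[:, sd == 0] = np.nan
        return m
    if measure == "spearman":
        return pairwise_scores(_rank_nd(profiles), "pearson")
    if measure in ("bray", "kld"):
        f = profiles.shape[0]
        closed = _close_nd(profiles)
        out = np.zeros((f, f))
        kernel = _bray_nd if measure == "bray" else _kld_nd
        for i in range(f):
            out[i, i + 1 :] = kernel(closed[i][None, :], closed[i + 1 :])
            out[i + 1 :, i] = out[i, i + 1 :]
        return out
    raise ValueError(f"unknown measure {measure!r}")


@dataclasses.dataclass
class CandidateSelection:
    measure: str
    top: list[Candidate]  # highest scores
    bottom: list[Candidate]  # lowest scores

    def merged(self) -> list[Candidate]:
        """Deduplicated union of the two tails (a pair can sit in both tails
        only when they overlap at saturation; the bottom-tail sign wins,
        deterministically)."""
        out: dict[tuple[int, int], Candidate] = {}
        for c in self.top:
            out[(c.i, c.j)] = c
        for c in self.bottom:
            out[(c.i, c.j)] = c
        return [out[p] for p in sorted(out)]


def select_candidates(
    scores: np.ndarray, measure: str, top_n: int = 1000, bottom_n: int = 1000
) -> CandidateSelection:
    """Top/bottom candidate edges of one measure's score matrix.

    For correlations the top (most positive) tail is copresence (+1) and the
    bottom is exclusion (-1); for dissimilarities small scores mean copresence
    and large scores exclusion. Ties break by lexicographic pair index so the
    selection is deterministic. Pairs with NaN scores (constant profiles under
    a correlation measure) are not scoreable and are skipped.
    """
    f = scores.shape[0]
    pairs = [(i, j) for i in range(f) for j in range(i + 1, f)]
    scored = [(scores[i, j], i, j) for i, j in pairs if np.isfinite(scores[i, j])]
    ascending = sorted(scored, key=lambda t: (t[0], t[1], t[2]))
    descending = sorted(scored, key=lambda t: (-t[0], t[1], t[2]))
    dissimilarity = measure not in CORRELATION_MEASURES
    top = [
        Candidate(i, j, measure, float(s), -1 if dissimilarity else +1)
        for s, i, j in descending[: min(top_n, len(scored))]
    ]
    bottom = [
        Candidate(i, j, measure, float(s), +1 if dissimilarity else -1)
        for s, i, j in ascending[: min(bottom_n, len(scored))]
    ]
    return CandidateSelection(measure, top, bottom)


# ---------------------------------------------------------------------------
# permutation + bootstrap significance


def _null_center(measure: str, null_scores: np.ndarray) -> np.ndarray:
    """Correlations are two-sided around zero; dissimilarities have no natural
    zero, so their null is centred at its own mean."""
    if measure in CORRELATION_MEASURES:
        return np.zeros(null_scores.shape[0])
    return null_scores.mean(axis=-1)


def edge_significance(
    counts: np.ndarray,
    candidates: list[Candidate],
    iterations: int = 1000,
    renormalize: bool = True,
    seed: int = 0,
    chunk: int = 32,
) -> list[dict]:
    """Permutation p and bootstrap interval for every candidate edge.

    ``counts`` is samples × features. With ``renormalize`` (the compositional
    null, default for taxon–taxon edges) it must be raw counts: the
    permutation null shuffles one feature of the pair across samples each
    iteration and re-closes every sample to proportions afterwards, so the
    null preserves closure. Without it the rows are scored exactly as given
    (pass relative abundances or intensities), which keeps the Spearman null
    invariant under order-preserving transforms of a feature's values.
    Two-sided p = (1 + #{|null - c| ≥ |observed - c|}) / (iterations + 1) with
    c the measure's null centre. The bootstrap resamples samples with
    replacement and records the 2.5/97.5 percentile interval; an edge whose
    interval covers the null centre is flagged unstable.
    """
    if iterations < 100:
        raise ValueError("iterations must be >= 100 (null too coarse below that)")
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    totals = counts.sum(axis=1)
    if renormalize and (totals <= 0).any():
        raise ValueError("samples with zero total")
    rel = counts / totals[:, None] if renormalize else counts

    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((iterations, n)), axis=1)
    boot_idx = rng.integers(0, n, size=(iterations, n))

    results: list[dict] = []
    by_measure: dict[str, list[Candidate]] = {}
    for c in candidates:
        by_measure.setdefault(c.measure, []).append(c)

    for measure, cands in by_measure.items():
        kernel = _KERNELS[measure]
        for start in range(0, len(cands), chunk):
            block = cands[start : start + chunk]
            ii = np.array([c.i for c in block])
            jj = np.array([c.j for c in block])
            obs = np.array([c.score for c in block])

            if renormalize:
                xi = counts[:, ii].T  # (E, n)
                yj = counts[:, jj].T
                xp = xi[:, perm_idx]  # (E, B, n)
                new_tot = totals[None, None, :] - xi[:, None, :] + xp
                null_x = xp / new_tot
                null_y = yj[:, None, :] / new_tot
            else:
                null_x = rel[:, ii].T[:, perm_idx]
                null_y = np.broadcast_to(rel[:, jj].T[:, None, :], null_x.shape)
            null_scores = kernel(null_x, null_y)  # (E, B)

            center = _null_center(measure, null_scores)
            exceed = (
                np.abs(null_scores - center[:, None]) >= np.abs(obs - center)[:, None]
            )
            # NaN null draws (constant permuted profile) count as non-exceeding
            p = (1 + np.nansum(np.where(np.isnan(null_scores), 0, exceed), axis=1)) / (
                iterations + 1
            )

            if renormalize:
                bx = counts[:, ii].T[:, boot_idx]
                by = counts[:, jj].T[:, boot_idx]
                btot = totals[boot_idx][None, :, :]
                boot_scores = kernel(bx / btot, by / btot)
            else:
                boot_scores = kernel(rel[:, ii].T[:, boot_idx], rel[:, jj].T[:, boot_idx])
            lo = np.nanpercentile(boot_scores, 2.5, axis=1)
            hi = np.nanpercentile(boot_scores, 97.5, axis=1)
            unstable = (lo <= center) & (center <= hi)

            for k, c in enumerate(block):
                results.append(
                    {
                        "candidate": c,
                        "p": float(p[k]),
                        "boot_low": float(lo[k]),
                        "boot_high": float(hi[k]),
                        "unstable": bool(unstable[k]),
                    }
                )
    return results


def consolidate_edges(
    sig_results: list[dict],
    feature_ids: list[str],
    q_threshold: float = 0.05,
    min_support: int = 2,
    node_type: str = "taxon",
) -> tuple[list[Edge], list[tuple[str, str]]]:
    """Merge per-measure survivors into the final edge list.

    BH runs within each measure across its candidates. An edge enters the
    final network iff it passes q < q_threshold in at least ``min_support``
    measures with one consistent sign; its reported p is Fisher's combination
    over the supporting measures, its score the mean supporting score for
    correlations (the Spearman rho when available). Edges whose supporting
    measures disagree in sign are dropped and returned in the conflict list.
    """
    from .screening import bh_adjust

    by_measure: dict[str, list[dict]] = {}
    for r in sig_results:
        by_measure.setdefault(r["candidate"].measure, []).append(r)
    for measure, rs in by_measure.items():
        qs = bh_adjust([r["p"] for r in rs])
        for r, q in zip(rs, qs):
            r["q"] = float(q)

    by_pair: dict[tuple[int, int], list[dict]] = {}
    for rs in by_measure.values():
        for r in rs:
            c = r["candidate"]
            by_pair.setdefault((c.i, c.j), []).append(r)

    edges: list[Edge] = []
    conflicts: list[tuple[str, str]] = []
    for (i, j), rs in sorted(by_pair.items()):
        supporting = [r for r in rs if r["q"] < q_threshold]
        if len(supporting) < min_support:
            continue
        signs = {r["candidate"].sign for r in supporting}
        src, tgt = feature_ids[i], feature_ids[j]
        if len(signs) > 1:
            conflicts.append((src, tgt))
            continue
        k = len(supporting)
        fisher_stat = -2 * sum(np.log(r["p"]) for r in supporting)
        combined_p = float(stats.chi2.sf(fisher_stat, 2 * k))
        spearman = [r for r in supporting if r["candidate"].measure == "spearman"]
        rep = spearman[0] if spearman else supporting[0]
        edges.append(
            Edge(
                source=src,
                target=tgt,
                source_type=node_type,
                target_type=node_type,
                measure="+".join(sorted(r["candidate"].measure for r in supporting)),
                score=float(rep["candidate"].score),
                sign=signs.pop(),
                p=combined_p,
                boot_low=float(rep["boot_low"]),
                boot_high=float(rep["boot_high"]),
                unstable=any(r["unstable"] for r in supporting),
                support=k,
            )
        )
    if edges:
        qs = bh_adjust([e.p for e in edges])
        for e, q in zip(edges, qs):
            e.q = float(q)
    return edges, conflicts


def conet(
    counts: np.ndarray,
    feature_ids: list[str],
    top_n: int = 1000,
    bottom_n: int = 1000,
    iterations: int = 1000,
    q_threshold: float = 0.05,
    min_support: int = 2,
    renormalize: bool = True,
    seed: int = 0,
) -> tuple[list[Edge], list[tuple[str, str]]]:
    """Full ensemble run: score → candidates → significance → consolidation."""
    counts = np.asarray(counts, dtype=float)
    rel = counts / counts.sum(axis=1, keepdims=True)
    profiles = rel.T  # features × samples
    candidates: list[Candidate] = []
    for measure in MEASURES:
        scores = pairwise_scores(profiles, measure)
        candidates.extend(select_candidates(scores, measure, top_n, bottom_n).merged())
    sig = edge_significance(
        counts if renormalize else rel,
        candidates, iterations=iterations, renormalize=renormalize, seed=seed,
    )
    return consolidate_edges(sig, feature_ids, q_threshold, min_support)
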