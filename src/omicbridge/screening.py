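"""Differential screening of taxa and metabolites.

The screen mirrors a supervised metabolomics workflow: PLS-DA (NIPALS PLS1 on
autoscaled predictors against a ±1-coded class vector) yields per-feature VIP
scores; a two-sided Wilcoxon rank-sum test yields p-values (exact null for
group sizes ≤ 10, tie-corrected normal approximation otherwise);
Benjamini–Hochberg adjusts within the screen. A feature is selected when its
VIP exceeds the threshold and, when a p cut is given, p falls below it.
Downstream, trend consistency intersects per-timepoint screens and the
reversal filter keeps features whose treated-group median moves back toward
the control median at every treatment timepoint.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceTable, FeatureTable, SampleMetadata


# ---------------------------------------------------------------------------
# abundance filtering and normalization


def filter_features(
    table: AbundanceTable,
    grouping: pd.Series,
    min_sum: float = 120,
    min_occurrence: int = 12,
) -> tuple[AbundanceTable, list[str]]:
    """Keep a taxon iff, within at least one condition, its count sum is at
    least ``min_sum`` and it occurs (count > 0) in at least ``min_occurrence``
    samples. Returns the filtered table and the discarded taxon ids."""
    grouping = grouping.reindex(table.samples)
    if grouping.isna().any():
        missing = grouping.index[grouping.isna()].tolist()
        raise ValueError(f"samples without a condition: {missing}")
    keep = np.zeros(len(table.taxa), dtype=bool)
    for condition, idx in grouping.groupby(grouping).groups.items():
        sub = table.counts.loc[idx]
        if sub.shape[0] == 0:
            raise ValueError(f"empty condition: {condition!r}")
        keep |= ((sub.sum(axis=0) >= min_sum) & ((sub > 0).sum(axis=0) >= min_occurrence)).values
    kept = [t for t, k in zip(table.taxa, keep) if k]
    discarded = [t for t, k in zip(table.taxa, keep) if not k]
    return AbundanceTable(table.counts[kept].copy()), discarded


def total_ion_normalize(table: FeatureTable) -> FeatureTable:
    """Divide each sample's intensities by the sample total (rows sum to 1)."""
    totals = table.values.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with non-positive total intensity: {bad}")
    return FeatureTable(table.values.div(totals, axis=0), table.annotation)


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS PLS1) and VIP


class DegenerateResponseError(ValueError):
    """The class labels are orthogonal to every predictor: PLS has no signal."""


@dataclasses.dataclass
class PlsModel:
    """Fitted NIPALS PLS1 model against a two-class response.

    Stores, per component: unit-norm weight vector w, predictor loadings p,
    response loading c, score vector t, and the response sum of squares SSY
    explained by that component — everything VIP needs — plus the autoscaling
    constants so the fit is reproducible.
    """

    weights: np.ndarray  # (A, p) unit-norm
    x_loadings: np.ndarray  # (A, p)
    y_loadings: np.ndarray  # (A,)
    scores: np.ndarray  # (n, A)
    ssy: np.ndarray  # (A,) explained response sum of squares
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    feature_ids: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]


def plsda_fit(X, y, n_components: int = 2, tol: float = 1e-10, max_iter: int = 500,
              feature_ids: list[str] | None = None) -> PlsModel:
    """Fit PLS-DA: NIPALS PLS1 on autoscaled X and ±1-coded, centred y.

    Constant predictors get unit scale (they then carry zero weight). For a
    univariate response NIPALS converges in a single pass; the iteration loop
    is retained with the stated tolerance for the general contract.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples × features)")
    classes = pd.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"each class needs >= 2 samples, got {counts}")
    n, p = X.shape
    if n_components > min(p, n - 1):
        raise ValueError("n_components must be <= min(n_features, n_samples - 1)")

    y_coded = np.where(y == classes[0], 1.0, -1.0)
    y_mean = y_coded.mean()
    yc = y_coded - y_mean
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1)
    x_scale[x_scale == 0] = 1.0
    E = (X - x_mean) / x_scale
    f = yc.copy()

    W = np.zeros((n_components, p))
    P = np.zeros((n_components, p))
    C = np.zeros(n_components)
    T = np.zeros((n, n_components))
    ssy = np.zeros(n_components)

    for a in range(n_components):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm < tol:
            raise DegenerateResponseError(
                f"component {a + 1}: response unexplained (degenerate weights)"
            )
        w /= norm
        for _ in range(max_iter):
            t = E @ w
            c = (t @ f) / (t @ t)
            w_new = E.T @ f
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        else:
            raise ValueError(f"NIPALS did not converge in component {a + 1}")
        t = E @ w
        tt = t @ t
        c = (t @ f) / tt
        p_load = (E.T @ t) / tt
        E = E - np.outer(t, p_load)
        f = f - c * t
        W[a], P[a], C[a], T[:, a] = w, p_load, c, t
        ssy[a] = c * c * tt

    return PlsModel(W, P, C, T, ssy, x_mean, x_scale, float(y_mean), feature_ids)


def vip_scores(model: PlsModel) -> np.ndarray:
    """VIP_j = sqrt( p Σ_a SSY_a (w_aj / ||w_a||)² / Σ_a SSY_a )."""
    if model.n_components < 1:
        raise ValueError("model has no components")
    total = model.ssy.sum()
    if total <= 0:
        raise ValueError("response unexplained: all SSY are zero")
    w_norm2 = (model.weights**2).sum(axis=1)
    contrib = (model.ssy[:, None] / w_norm2[:, None]) * model.weights**2
    return np.sqrt(model.n_features * contrib.sum(axis=0) / total)


# ---------------------------------------------------------------------------
# rank-sum test, BH, screens


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p: exact null when both groups ≤ 10 and
    there are no cross-group ties, else normal approximation with tie
    correction (and continuity correction)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (max(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up: q_(i) = min_{j ≥ i} m p_(j) / j, capped at
    1, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclasses.dataclass
class ScreenRecord:
    feature: str
    timepoint: float
    vip: float
    p: float
    q: float
    direction: int  # +1 disease median > control median, -1 below, 0 tie
    selected: bool


def differential_screen(
    values: pd.DataFrame,
    grouping: pd.Series,
    vip_threshold: float,
    p_threshold: float | None = None,
    n_components: int = 2,
    timepoint: float = float("nan"),
    case_group: str | None = None,
) -> list[ScreenRecord]:
    """Screen one timepoint's two-group comparison.

    ``values``: samples × features (relative abundances or normalized
    intensities). ``grouping``: per-sample group label, exactly two levels;
    ``case_group`` names the level whose median defines direction +1 when
    above the other (defaults to the second level in sorted label order;
    pass it explicitly for meaningful signs).
    """
    grouping = grouping.reindex(values.index)
    levels = sorted(pd.unique(grouping.dropna()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    if case_group is None:
        case_group = levels[1]
    control_group = levels[0] if case_group == levels[1] else levels[1]
    case_mask = (grouping == case_group).values
    ctrl_mask = (grouping == control_group).values
    if case_mask.sum() < 2 or ctrl_mask.sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    X = values.values.astype(float)
    try:
        model = plsda_fit(
            X, grouping.values, n_components=min(n_components, min(X.shape[1], X.shape[0] - 1)),
            feature_ids=list(values.columns),
        )
        vips = vip_scores(model)
    except DegenerateResponseError:
        # labels orthogonal to every predictor: nothing discriminates
        vips = np.zeros(X.shape[1])

    p_raw = np.array(
        [rank_sum_test(X[case_mask, j], X[ctrl_mask, j]) for j in range(X.shape[1])]
    )
    q = bh_adjust(p_raw)
    case_med = np.median(X[case_mask], axis=0)
    ctrl_med = np.median(X[ctrl_mask], axis=0)
    direction = np.sign(case_med - ctrl_med).astype(int)

    records = []
    for j, feature in enumerate(values.columns):
        selected = vips[j] > vip_threshold and (p_threshold is None or p_raw[j] < p_threshold)
        records.append(
            ScreenRecord(
                feature=str(feature),
                timepoint=timepoint,
                vip=float(vips[j]),
                p=float(p_raw[j]),
                q=float(q[j]),
                direction=int(direction[j]),
                selected=bool(selected),
            )
        )
    return records


def screen_to_frame(records: list[ScreenRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


@dataclasses.dataclass
class TrendResult:
    feature: str
    directions: list[int]  # per timepoint, ordered
    selected_at: list[bool]
    consistent: bool
    overall_direction: int


def trend_consistency(screens: list[list[ScreenRecord]]) -> list[TrendResult]:
    """Intersect per-timepoint screens: a feature is trend-consistent iff it is
    selected at every timepoint with the same nonzero direction throughout.
    A feature missing from a timepoint's screen counts as not selected."""
    if len(screens) < 2:
        raise ValueError("need screens from at least two timepoints")
    universe: list[str] = []
    seen = set()
    for screen in screens:
        for r in screen:
            if r.feature not in seen:
                universe.append(r.feature)
                seen.add(r.feature)
    by_tp = [{r.feature: r for r in screen} for screen in screens]
    results = []
    for feature in universe:
        recs = [tp.get(feature) for tp in by_tp]
        directions = [r.direction if r is not None else 0 for r in recs]
        selected = [r.selected if r is not None else False for r in recs]
        consistent = (
            all(selected)
            and directions[0] != 0
            and all(d == directions[0] for d in directions)
        )
        results.append(
            TrendResult(
                feature=feature,
                directions=directions,
                selected_at=selected,
                consistent=consistent,
                overall_direction=directions[0] if consistent else 0,
            )
        )
    return results


def trend_to_frame(results: list[TrendResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "directions": ",".join(str(d) for d in r.directions),
                "selected_at": ",".join(str(int(s)) for s in r.selected_at),
                "consistent": r.consistent,
                "overall_direction": r.overall_direction,
            }
            for r in results
        ]
    )


def reversal_screen(
    values: pd.DataFrame,
    metadata: SampleMetadata,
    features: list[str],
    treatment_timepoints: list[float],
    groups: tuple[str, str, str] = ("WT", "Tg", "TgR"),
) -> pd.DataFrame:
    """Treatment-reversal filter.

    A feature is reversed iff at EVERY treatment timepoint the treated-group
    median lies strictly closer to the control median than the disease median
    does. Reports per-timepoint shrinkage ratios
    |median(treated) - median(control)| / |median(disease) - median(control)|.
    """
    control, disease, treated = groups
    meta = metadata.frame
    rows = []
    for feature in features:
        ratios = []
        reversed_flag = True
        for tp in treatment_timepoints:
            at_tp = meta[meta["timepoint"] == tp]
            meds = {}
            for g in (control, disease, treated):
                samples = at_tp.index[at_tp["group"] == g]
                if len(samples) == 0:
                    raise ValueError(f"group {g!r} missing at timepoint {tp}")
                meds[g] = float(values.loc[samples, feature].median())
            dis_gap = abs(meds[disease] - meds[control])
            trt_gap = abs(meds[treated] - meds[control])
            ratios.append(trt_gap / dis_gap if dis_gap > 0 else float("inf"))
            if not trt_gap < dis_gap:
                reversed_flag = False
        rows.append(
            {
                "feature": feature,
                "reversed": reversed_flag,
                **{f"shrinkage_t{tp}": r for tp, r in zip(treatment_timepoints, ratios)},
            }
        )
    return pd.DataFrame(rows)
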