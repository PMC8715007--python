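"""Tripartite taxon–metabolite–indicator correlation network and bridge ranking.

Every cross-layer feature pair is tested with both Pearson and Spearman
correlation (analytic two-sided p); Benjamini–Hochberg runs jointly across all
cross-layer tests per method; an edge is retained only when both methods pass
the q threshold with agreeing sign. A *bridge metabolite* is a metabolite with
at least one significant taxon edge and at least one significant indicator
edge — the candidate mediator between a drug-responsive microbe and a
pathological readout — ranked by total degree, then summed |rho|, then id.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .network import Edge
from .screening import bh_adjust


@dataclasses.dataclass
class TripartiteNetwork:
    nodes: dict[str, str]  # id -> layer (taxon | metabolite | indicator)
    edges: list[Edge]

    def edges_between(self, layer_a: str, layer_b: str) -> list[Edge]:
        want = {layer_a, layer_b}
        return [e for e in self.edges if {e.source_type, e.target_type} == want]

    def degree(self, node: str) -> int:
        return sum(1 for e in self.edges if node in (e.source, e.target))


def _column_correlations(a: np.ndarray, b: np.ndarray, method: str) -> np.ndarray:
    """Correlation matrix between columns of a (n×p) and b (n×q)."""
    if method == "spearman":
        a = stats.rankdata(a, axis=0)
        b = stats.rankdata(b, axis=0)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    denom = np.outer(
        np.sqrt((ac**2).sum(axis=0)), np.sqrt((bc**2).sum(axis=0))
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, ac.T @ bc / denom, np.nan)
    return np.clip(r, -1.0, 1.0)


def _correlation_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t-distribution with n-2 df (exact-fit r = ±1 → 0)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.where(np.isnan(r), np.nan, p)


def tripartite_network(
    taxa_values: pd.DataFrame,
    metabolite_values: pd.DataFrame,
    indicator_values: pd.DataFrame,
    q_threshold: float = 0.05,
    include_taxon_taxon: bool = False,
) -> TripartiteNetwork:
    """Build the significant cross-layer network.

    Inputs are samples × features tables; they are joined on shared sample
    ids (at least 4 required). Constant features test as NaN and never form
    edges. Edge weight is the Spearman rho.
    """
    shared = taxa_values.index.intersection(metabolite_values.index).intersection(
        indicator_values.index
    )
    if len(shared) < 4:
        raise ValueError(f"need at least 4 shared samples, found {len(shared)}")
    layers = {
        "taxon": taxa_values.loc[shared],
        "metabolite": metabolite_values.loc[shared],
        "indicator": indicator_values.loc[shared],
    }
    n = len(shared)

    layer_pairs = [("taxon", "metabolite"), ("taxon", "indicator"), ("metabolite", "indicator")]
    if include_taxon_taxon:
        layer_pairs.append(("taxon", "taxon"))

    tests = []  # (source, target, source_type, target_type, r_pearson, r_spearman)
    for la, lb in layer_pairs:
        a, b = layers[la], layers[lb]
        rp = _column_correlations(a.values, b.values, "pearson")
        rs = _column_correlations(a.values, b.values, "spearman")
        for i, fa in enumerate(a.columns):
            j_start = i + 1 if la == lb else 0
            for j in range(j_start, b.shape[1]):
                if np.isnan(rp[i, j]) or np.isnan(rs[i, j]):
                    continue
                tests.append((str(fa), str(b.columns[j]), la, lb, rp[i, j], rs[i, j]))

    if not tests:
        return TripartiteNetwork(_all_nodes(layers), [])

    rp_all = np.array([t[4] for t in tests])
    rs_all = np.array([t[5] for t in tests])
    pp = _correlation_p(rp_all, n)
    ps = _correlation_p(rs_all, n)
    qp = bh_adjust(pp)
    qs = bh_adjust(ps)

    edges = []
    for k, (src, tgt, ta, tb, rpk, rsk) in enumerate(tests):
        if qp[k] >= q_threshold or qs[k] >= q_threshold:
            continue
        sp, ss = np.sign(rpk), np.sign(rsk)
        if sp == 0 or ss == 0 or sp != ss:
            continue
        edges.append(
            Edge(
                source=src,
                target=tgt,
                source_type=ta,
                target_type=tb,
                measure="pearson+spearman",
                score=float(rsk),
                sign=int(ss),
                p=float(max(pp[k], ps[k])),
                q=float(max(qp[k], qs[k])),
                support=2,
            )
        )
    return TripartiteNetwork(_all_nodes(layers), edges)


def _all_nodes(layers: dict[str, pd.DataFrame]) -> dict[str, str]:
    return {str(f): layer for layer, table in layers.items() for f in table.columns}


def rank_bridge_metabolites(network: TripartiteNetwork) -> pd.DataFrame:
    """Rank bridge metabolites (≥1 taxon edge AND ≥1 indicator edge).

    Ordered by total degree (descending), then summed |rho| over incident
    edges (descending), then metabolite id (ascending). Non-bridges excluded.
    """
    stats_by_met: dict[str, dict] = {}
    for e in network.edges:
        for node, node_type, other_type in (
            (e.source, e.source_type, e.target_type),
            (e.target, e.target_type, e.source_type),
        ):
            if node_type != "metabolite":
                continue
            rec = stats_by_met.setdefault(
                node, {"taxon_edges": 0, "indicator_edges": 0, "metabolite_edges": 0, "abs_rho": 0.0}
            )
            rec[f"{other_type}_edges"] += 1
            rec["abs_rho"] += abs(e.score)
    rows = []
    for met, rec in stats_by_met.items():
        if rec["taxon_edges"] >= 1 and rec["indicator_edges"] >= 1:
            degree = rec["taxon_edges"] + rec["indicator_edges"] + rec["metabolite_edges"]
            rows.append(
                {
                    "metabolite": met,
                    "degree": degree,
                    "taxon_edges": rec["taxon_edges"],
                    "indicator_edges": rec["indicator_edges"],
                    "sum_abs_rho": rec["abs_rho"],
                }
            )
    frame = pd.DataFrame(
        rows, columns=["metabolite", "degree", "taxon_edges", "indicator_edges", "sum_abs_rho"]
    )
    if frame.empty:
        return frame
    return frame.sort_values(
        ["degree", "sum_abs_rho", "metabolite"], ascending=[False, False, True]
    ).reset_index(drop=True)
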