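"""Absolute quantification against qPCR standard curves and responsiveness calls.

A standard curve regresses Ct on log10 copy number; amplification efficiency
is E = 10^(-1/slope) - 1 (slope -3.32 ⇔ perfect doubling, E = 100%). Unknowns
are quantified by inverting the curve. A candidate taxon is called
drug-responsive when the treated group differs from the disease group
(two-sided rank-sum p < α) AND the treated median lies strictly closer to the
control median than the disease median does.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .screening import rank_sum_test


@dataclasses.dataclass
class StandardCurve:
    slope: float  # Ct per log10 copies; < 0 for a valid assay
    intercept: float  # Ct at one copy
    r_squared: float
    efficiency: float  # E = 10^(-1/slope) - 1

    @property
    def valid(self) -> bool:
        return self.slope < 0


def fit_standard_curve(log10_copies, ct_values) -> StandardCurve:
    """Ordinary least squares Ct = intercept + slope · log10(copies)."""
    x = np.asarray(log10_copies, dtype=float)
    y = np.asarray(ct_values, dtype=float)
    if x.size != y.size:
        raise ValueError("log10_copies and ct_values must align")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct dilution points")
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    efficiency = 10 ** (-1.0 / slope) - 1.0 if slope != 0 else float("nan")
    return StandardCurve(
        slope=slope,
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency=float(efficiency),
    )


def quantify_copies(ct, curve: StandardCurve):
    """Invert the curve: copies = 10^((ct - intercept) / slope)."""
    if not curve.valid:
        raise ValueError("invalid assay: standard-curve slope must be negative")
    ct = np.asarray(ct, dtype=float)
    out = 10 ** ((ct - curve.intercept) / curve.slope)
    return float(out) if out.ndim == 0 else out


def validate_responsive(
    copies_by_group: dict[str, dict[str, np.ndarray]],
    alpha: float = 0.05,
    groups: tuple[str, str, str] = ("WT", "Tg", "TgR"),
) -> list[dict]:
    """Call drug-responsive taxa from absolute copy numbers.

    ``copies_by_group``: {taxon: {group: copy-number array}}. Responsive ⇔
    disease-vs-treated rank-sum p < alpha AND |median(treated) - median(control)|
    < |median(disease) - median(control)|.
    """
    control, disease, treated = groups
    calls = []
    for taxon, per_group in copies_by_group.items():
        for g in (control, disease, treated):
            if g not in per_group:
                raise ValueError(f"taxon {taxon!r}: group {g!r} missing")
            if len(per_group[g]) < 3:
                raise ValueError(f"taxon {taxon!r}: group {g!r} needs >= 3 measurements")
        p = rank_sum_test(per_group[disease], per_group[treated])
        med = {g: float(np.median(per_group[g])) for g in (control, disease, treated)}
        closer = abs(med[treated] - med[control]) < abs(med[disease] - med[control])
        responsive = p < alpha and closer
        direction = (
            "reduced toward control"
            if med[disease] > med[control]
            else "increased toward control"
        )
        calls.append(
            {
                "taxon": taxon,
                "p": float(p),
                "median_control": med[control],
                "median_disease": med[disease],
                "median_treated": med[treated],
                "responsive": bool(responsive),
                "direction": direction if responsive else "",
            }
        )
    return calls
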