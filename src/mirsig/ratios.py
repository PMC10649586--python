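"""Up/down miRNA expression ratios and their ROC/Youden diagnostics.

A ratio divides the relative expression of an up-regulated miRNA by that of
a down-regulated one, per sample.  Because both numerator and denominator
were divided by the same per-sample reference, the reference cancels — the
ratio is identical whether computed from normalized values or raw Cqs,
which is the point of the approach.

Each ratio is scored as a malignant-vs-borderline classifier: an ROC curve
over single thresholds (rule: call malignant when the ratio exceeds the
threshold), its area under the curve, and the operating point maximizing
the Youden index J = sensitivity + specificity − 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GROUP_BORDERLINE, GROUP_MALIGNANT
from .qpcr import RelativeExpression, differential_test


@dataclass
class RatioMatrix:
    """Per-sample values of all up/down ratios (linear scale, > 0).

    ``values``: ratio x sample DataFrame, index "up_id/down_id";
    ``provenance``: per ratio, the constituent up and down miRNA ids.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame  # columns: up, down

    @property
    def ratio_ids(self) -> list[str]:
        return list(self.values.index)

    def members(self, ratio_id: str) -> tuple[str, str]:
        row = self.provenance.loc[ratio_id]
        return row["up"], row["down"]

    @property
    def log2(self) -> pd.DataFrame:
        return np.log2(self.values)


@dataclass
class RocResult:
    """ROC curve on the explicit threshold grid, with Youden summaries."""

    thresholds: np.ndarray  # ascending, includes -inf and +inf
    sensitivity: np.ndarray  # fraction of M strictly above each threshold
    specificity: np.ndarray  # fraction of B at or below each threshold
    auc: float

    @property
    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def build_ratios(
    rel: RelativeExpression | pd.DataFrame, up: list[str], down: list[str]
) -> RatioMatrix:
    """All |up| x |down| per-sample expression ratios.

    ``rel`` may be a :class:`RelativeExpression` or any miRNA x sample
    DataFrame of positive linear-scale values.  ``up`` and ``down`` must be
    disjoint and fully measured; a missing value in either member propagates
    as missing for that sample's ratio.
    """
    overlap = set(up) & set(down)
    if overlap:
        raise ValueError(f"up and down sets overlap: {sorted(overlap)}")
    if not up or not down:
        raise ValueError("need at least one up and one down miRNA")
    lin = rel.linear if isinstance(rel, RelativeExpression) else rel
    missing = [m for m in list(up) + list(down) if m not in lin.index]
    if missing:
        raise KeyError(f"miRNAs not measured: {missing}")
    rows, prov = [], []
    for u in up:
        for d in down:
            rows.append((lin.loc[u] / lin.loc[d]).rename(f"{u}/{d}"))
            prov.append({"ratio_id": f"{u}/{d}", "up": u, "down": d})
    return RatioMatrix(
        values=pd.DataFrame(rows),
        provenance=pd.DataFrame(prov).set_index("ratio_id"),
    )


def roc(values: pd.Series, groups: pd.Series) -> RocResult:
    """ROC curve for the rule "call malignant when value > threshold".

    Thresholds sit at midpoints of consecutive sorted unique values plus
    ±inf.  The orientation is fixed malignant-high and never auto-flipped:
    an AUC below 0.5 is reported as-is.  The trapezoid AUC over this grid
    equals the rank statistic (fraction of (M, B) pairs with the malignant
    value higher, ties counted one half).
    """
    values = pd.Series(values).dropna()
    groups = pd.Series(groups).loc[values.index]
    v = values.to_numpy(dtype=float)
    is_m = (groups == GROUP_MALIGNANT).to_numpy()
    is_b = (groups == GROUP_BORDERLINE).to_numpy()
    if not is_m.any() or not is_b.any():
        raise ValueError("both groups must be non-empty")
    uniq = np.unique(v)
    thresholds = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    sens = np.array([(is_m & (v > t)).sum() / is_m.sum() for t in thresholds])
    spec = np.array([(is_b & (v <= t)).sum() / is_b.sum() for t in thresholds])
    # ascending thresholds sweep FPR from 1 down to 0; integrate TPR dFPR
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    return RocResult(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc)


def youden_optimal(result: RocResult) -> tuple[float, float, float, float]:
    """Operating point maximizing J = sensitivity + specificity − 1.

    Ties break toward higher specificity, then the lower threshold.
    Returns (threshold, J*, sensitivity*, specificity*).
    """
    j = result.youden
    order = sorted(
        range(len(j)),
        key=lambda i: (-j[i], -result.specificity[i], result.thresholds[i]),
    )
    best = order[0]
    return (
        float(result.thresholds[best]),
        float(j[best]),
        float(result.sensitivity[best]),
        float(result.specificity[best]),
    )


def test_ratios(ratios: RatioMatrix, groups: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Equal-variance two-sample t-test per ratio, on the log2 scale.

    Two-sided at ``alpha`` with no multiplicity adjustment, mirroring the
    single-stage design the method was built for.
    """
    log2v = ratios.log2
    rows = []
    for rid in log2v.index:
        t, p = differential_test(log2v.loc[rid], groups)
        rows.append({"ratio_id": rid, "t": t, "p": p, "significant": p < alpha})
    return pd.DataFrame(rows).set_index("ratio_id")


def summarize_ratios(ratios: RatioMatrix, groups: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Per-ratio diagnostics: t, p, AUC and the Youden operating point."""
    tests = test_ratios(ratios, groups, alpha=alpha)
    rows = []
    for rid in ratios.values.index:
        r = roc(ratios.values.loc[rid], groups)
        thr, j, sens, spec = youden_optimal(r)
        rows.append(
            {
                "ratio_id": rid,
                "auc": r.auc,
                "threshold": thr,
                "youden_j": j,
                "sensitivity": sens,
                "specificity": spec,
            }
        )
    summary = pd.DataFrame(rows).set_index("ratio_id")
    return tests.join(summary)


def youden_thresholds(ratios: RatioMatrix, groups: pd.Series) -> pd.Series:
    """Youden-optimal threshold for every ratio (used by pair classification)."""
    return pd.Series(
        {rid: youden_optimal(roc(ratios.values.loc[rid], groups))[0] for rid in ratios.values.index},
        name="threshold",
    )
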