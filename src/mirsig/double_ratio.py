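"""Pairwise combination of thresholded miRNA ratios ("double ratios").

Single up/down ratios rarely separate the two tumor groups perfectly; pairs
of ratios, each with its own Youden-optimal threshold, can compensate each
other's misclassifications.  Pairs whose two ratios share a miRNA are not
admissible (fewer than four distinct miRNAs): a shared member makes the two
coordinates strongly dependent, so only pairs built from four distinct
miRNAs are scored.

For admissible pairs the per-sample calls from the two thresholds combine
under a configurable rule — AND (default: call malignant only when both
ratios exceed their thresholds), OR, or SUM (malignant when the summed log2
margins are positive) — and the pair is scored by its resubstitution error
count over all samples, the quantity rendered as the error heat map.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .datatypes import GROUP_BORDERLINE, GROUP_MALIGNANT
from .ratios import RatioMatrix, youden_thresholds

RULES = ("and", "or", "sum")


def pair_count_closed_form(a: int, b: int) -> int:
    """Number of admissible pairs from a up- and b down-miRNAs.

    All unordered pairs of distinct ratios minus those sharing the up member
    (same u, two downs) or the down member: C(ab,2) − a·C(b,2) − b·C(a,2).
    """
    return comb(a * b, 2) - a * comb(b, 2) - b * comb(a, 2)


def enumerate_pairs(ratios: RatioMatrix, min_distinct: int = 4) -> pd.DataFrame:
    """All unordered ratio pairs with >= ``min_distinct`` distinct miRNAs.

    For u/d ratios a pair involves at most 4 miRNAs, so ``min_distinct=4``
    keeps exactly the pairs sharing no miRNA and anything stricter is empty.
    """
    rows = []
    for r1, r2 in combinations(ratios.ratio_ids, 2):
        members = set(ratios.members(r1)) | set(ratios.members(r2))
        if len(members) >= min_distinct:
            rows.append({"ratio_1": r1, "ratio_2": r2, "n_distinct": len(members)})
    return pd.DataFrame(rows, columns=["ratio_1", "ratio_2", "n_distinct"])


def _log2_margin(values: pd.Series, threshold: float) -> pd.Series:
    """Signed log2 distance above the threshold (+inf/−inf for infinite t)."""
    if np.isneginf(threshold) or threshold <= 0:
        return pd.Series(np.inf, index=values.index).where(values.notna())
    if np.isposinf(threshold):
        return pd.Series(-np.inf, index=values.index).where(values.notna())
    return np.log2(values) - np.log2(threshold)


def classify_pair(
    values_1: pd.Series,
    values_2: pd.Series,
    threshold_1: float,
    threshold_2: float,
    rule: str = "and",
) -> pd.Series:
    """Per-sample call from two thresholded ratios.

    Rules (calls on the strict ">" side; a sample exactly on a threshold
    falls to the borderline side):

    - ``and``: malignant iff both ratios exceed their thresholds;
    - ``or``: malignant iff either does;
    - ``sum``: malignant iff the summed log2 margins are positive.

    Samples with a missing value in either ratio get a missing (NaN) call.
    """
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}, got {rule!r}")
    v1, v2 = pd.Series(values_1), pd.Series(values_2).loc[pd.Series(values_1).index]
    defined = v1.notna() & v2.notna()
    if rule == "and":
        call_m = (v1 > threshold_1) & (v2 > threshold_2)
    elif rule == "or":
        call_m = (v1 > threshold_1) | (v2 > threshold_2)
    else:
        call_m = (_log2_margin(v1, threshold_1) + _log2_margin(v2, threshold_2)) > 0
    labels = pd.Series(
        np.where(call_m, GROUP_MALIGNANT, GROUP_BORDERLINE), index=v1.index, dtype=object
    )
    labels[~defined] = np.nan
    return labels


@dataclass
class PairErrorMatrix:
    """Classification-error counts for every admissible ratio pair.

    ``pairs`` columns: ``ratio_1``, ``ratio_2``, ``n_distinct``, ``errors``,
    ``n_samples`` (samples with both ratios defined).  ``predictions`` holds
    the per-pair per-sample calls; ``rule`` and ``thresholds`` record how the
    calls were made.
    """

    pairs: pd.DataFrame
    predictions: pd.DataFrame  # index: pair position, columns: sample ids
    rule: str
    thresholds: pd.Series
    n_samples_total: int

    def square(self) -> pd.DataFrame:
        """Symmetric ratio x ratio error matrix (NaN where inadmissible).

        Ratios are ordered by their up-member then down-member, giving the
        block structure of the published heat map.
        """
        ids = sorted(self.thresholds.index)
        mat = pd.DataFrame(np.nan, index=ids, columns=ids)
        for row in self.pairs.itertuples():
            mat.loc[row.ratio_1, row.ratio_2] = row.errors
            mat.loc[row.ratio_2, row.ratio_1] = row.errors
        return mat


def error_matrix(
    ratios: RatioMatrix,
    groups: pd.Series,
    rule: str = "and",
    min_distinct: int = 4,
    thresholds: pd.Series | None = None,
) -> PairErrorMatrix:
    """Misclassification counts for all admissible pairs.

    Thresholds default to each ratio's own Youden optimum (reused as-is,
    never re-optimized jointly for the pair).  Samples missing either ratio
    are excluded from that pair's count and reflected in ``n_samples``.
    """
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}, got {rule!r}")
    groups = pd.Series(groups).loc[ratios.values.columns]
    if thresholds is None:
        thresholds = youden_thresholds(ratios, groups)
    admissible = enumerate_pairs(ratios, min_distinct=min_distinct)
    pairs = admissible.copy()
    if admissible.empty:
        pairs["errors"] = pd.Series(dtype=int)
        pairs["n_samples"] = pd.Series(dtype=int)
        return PairErrorMatrix(
            pairs=pairs,
            predictions=pd.DataFrame(columns=ratios.values.columns),
            rule=rule,
            thresholds=thresholds,
            n_samples_total=len(groups),
        )

    # vectorized over all pairs: per-ratio call matrices, then combine
    values = ratios.values.to_numpy(dtype=float)
    t = thresholds.loc[ratios.values.index].to_numpy(dtype=float)
    defined = np.isfinite(values)
    with np.errstate(invalid="ignore"):
        above = values > t[:, None]
    pos = {rid: i for i, rid in enumerate(ratios.values.index)}
    i_idx = admissible["ratio_1"].map(pos).to_numpy()
    j_idx = admissible["ratio_2"].map(pos).to_numpy()
    if rule == "and":
        call_m = above[i_idx] & above[j_idx]
    elif rule == "or":
        call_m = above[i_idx] | above[j_idx]
    else:
        margins = np.empty_like(values)
        for r in range(len(t)):
            margins[r] = _log2_margin(
                pd.Series(values[r], index=ratios.values.columns), t[r]
            ).to_numpy()
        with np.errstate(invalid="ignore"):
            call_m = (margins[i_idx] + margins[j_idx]) > 0
    pair_defined = defined[i_idx] & defined[j_idx]
    is_m = (groups == GROUP_MALIGNANT).to_numpy()
    wrong = (call_m != is_m[None, :]) & pair_defined
    pairs["errors"] = wrong.sum(axis=1).astype(int)
    pairs["n_samples"] = pair_defined.sum(axis=1).astype(int)
    labels = np.where(call_m, GROUP_MALIGNANT, GROUP_BORDERLINE).astype(object)
    labels[~pair_defined] = np.nan
    predictions = pd.DataFrame(labels, columns=ratios.values.columns)
    return PairErrorMatrix(
        pairs=pairs,
        predictions=predictions,
        rule=rule,
        thresholds=thresholds,
        n_samples_total=len(groups),
    )


def perfect_pairs(matrix: PairErrorMatrix) -> tuple[pd.DataFrame, float]:
    """Zero-error pairs and their fraction of all admissible pairs."""
    if matrix.pairs.empty:
        return matrix.pairs.copy(), 0.0
    zero = matrix.pairs[matrix.pairs["errors"] == 0].reset_index(drop=True)
    return zero, len(zero) / len(matrix.pairs)


def plot_error_heatmap(matrix: PairErrorMatrix, path=None):
    """Render the pair-error heat map (ratios blocked by up-member)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    square = matrix.square()
    fig, ax = plt.subplots(figsize=(max(6, len(square) * 0.25),) * 2)
    im = ax.imshow(square.to_numpy(), cmap="viridis_r", interpolation="nearest")
    ax.set_xticks(range(len(square)), square.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(square)), square.index, fontsize=6)
    fig.colorbar(im, ax=ax, label=f"errors ({matrix.rule.upper()} rule)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
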