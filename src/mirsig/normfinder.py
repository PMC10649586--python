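"""Grouped reference-gene stability and geometric-mean normalization.

Candidate reference miRNAs are scored with a grouped stability model in the
NormFinder family: after removing each sample's overall level, a candidate's
instability has two sources — how strongly its level interacts with the
group (a systematic group effect, fatal for a normalizer) and how noisy it
is within groups.  Both are combined into a single stability value ``rho``
(log2 units, lower = more stable).

Model, for log2 values x of candidate gene i in sample j of group g:

1. centre each sample over the candidate panel: ``z_igj = x_igj − mean_i x``;
2. per gene × group: mean ``zbar_ig`` and residual variance ``v_ig``
   (denominator ``k_g − 1``);
3. raw gene×group interaction ``d_ig = zbar_ig − zbar_i. − zbar_.g + zbar_..``;
4. method-of-moments interaction variance, truncated at zero:
   ``tau2 = max(0, sum d_ig^2 / ((n−1)(G−1)) − mean_ig(v_ig / k_g))``;
5. shrink the interactions: ``d~_ig = d_ig * tau2 / (tau2 + v_ig / k_g)``;
6. stability ``rho_i = (1/G) * sum_g (|d~_ig| + sqrt((v_ig/k_g) * tau2 / (tau2 + v_ig/k_g)))``.

The chosen normalizers define a per-sample normalization factor equal to the
arithmetic mean of their log2 values — the log of their geometric mean on
the linear scale — which is subtracted from every miRNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix


@dataclass
class StabilityResult:
    """Stability values and the model quantities behind them."""

    rho: pd.Series  # per-gene stability, log2 units, >= 0
    d_shrunk: pd.DataFrame  # shrunken gene x group deviations
    intra_var: pd.DataFrame  # residual variance per gene x group
    tau2: float  # gene-by-group interaction variance (truncated)
    mean_expr: pd.Series  # overall mean log2 expression per gene

    def ranked(self) -> pd.Series:
        return self.rho.sort_values(kind="stable")


@dataclass
class NormalizerSet:
    """An ordered reference panel and its per-sample log2 factors."""

    mirna_ids: list[str]
    factors: pd.Series  # per sample: mean of the normalizers' log2 values


def stability_values(
    matrix: ExpressionMatrix, candidate_ids: list[str] | None = None
) -> StabilityResult:
    """Grouped stability value for each candidate reference miRNA.

    ``candidate_ids`` restricts the panel (default: every miRNA in the
    matrix).  Each group must contribute at least 2 samples and the panel at
    least 3 genes, otherwise the variance components are undefined.
    """
    sub = matrix if candidate_ids is None else matrix.subset(candidate_ids)
    groups = sub.groups
    labels = sub.group_labels
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ValueError(f"each group needs >= 2 samples, got {counts.to_dict()}")
    if sub.values.shape[0] < 3:
        raise ValueError("need at least 3 candidate miRNAs")

    # 1. centre each sample over the candidate panel
    z = sub.values - sub.values.mean(axis=0)

    # 2. per gene x group means and residual variances
    zbar = z.T.groupby(groups).mean().T[labels]
    v = z.T.groupby(groups).var(ddof=1).T[labels]
    k = counts[labels].astype(float)

    # 3. two-way interaction of the gene x group means
    d = zbar.sub(zbar.mean(axis=1), axis=0).sub(zbar.mean(axis=0), axis=1) + zbar.values.mean()

    # 4. method-of-moments interaction variance, truncated at zero
    n_genes, n_groups = zbar.shape
    v_over_k = v.div(k, axis=1)
    tau2 = float(
        max(
            0.0,
            (d.values**2).sum() / ((n_genes - 1) * (n_groups - 1)) - v_over_k.values.mean(),
        )
    )

    # 5./6. shrink and combine with the sampling error of the deviation
    denom = tau2 + v_over_k
    shrink = (tau2 / denom).where(denom > 0, 0.0)
    d_shrunk = d * shrink
    se = np.sqrt(v_over_k * shrink)
    rho = (d_shrunk.abs() + se).mean(axis=1)
    rho.name = "rho"

    return StabilityResult(
        rho=rho,
        d_shrunk=d_shrunk,
        intra_var=v,
        tau2=tau2,
        mean_expr=sub.values.mean(axis=1).rename("mean_expr"),
    )


def normalization_factor(matrix: ExpressionMatrix, mirna_ids: list[str]) -> pd.Series:
    """Per-sample log2 normalization factor: mean of the normalizers' values
    (log2 of their geometric mean on the linear scale)."""
    missing = [m for m in mirna_ids if m not in matrix.values.index]
    if missing:
        raise KeyError(f"normalizers missing from matrix: {missing}")
    return matrix.values.loc[list(mirna_ids)].mean(axis=0).rename("factor")


def select_normalizers(
    stab: StabilityResult,
    matrix: ExpressionMatrix,
    expr_min: float = 5.0,
    stability_max: float = 0.25,
    k: int = 3,
    probe_list: set[str] | None = None,
) -> NormalizerSet:
    """The k most stable candidates passing expression/stability/probe filters.

    Filters: overall mean log2 expression >= ``expr_min``; stability value
    strictly below ``stability_max``; id in ``probe_list`` when one is given.
    Ties in stability break toward higher mean expression, then lexicographic
    id.
    """
    table = pd.DataFrame({"rho": stab.rho, "mean_expr": stab.mean_expr})
    passing = table[(table["mean_expr"] >= expr_min) & (table["rho"] < stability_max)]
    if probe_list is not None:
        passing = passing[passing.index.isin(set(probe_list))]
    if len(passing) < k:
        raise ValueError(
            f"only {len(passing)} candidate(s) pass the normalizer filters, need {k}"
        )
    ordered = passing.sort_values(
        by=["rho", "mean_expr"],
        ascending=[True, False],
        kind="stable",
    )
    # lexicographic id as the final tie-break
    ordered = ordered.loc[
        sorted(ordered.index, key=lambda m: (ordered.at[m, "rho"], -ordered.at[m, "mean_expr"], m))
    ]
    ids = list(ordered.index[:k])
    return NormalizerSet(mirna_ids=ids, factors=normalization_factor(matrix, ids))


def normalize(matrix: ExpressionMatrix, normalizers: NormalizerSet) -> ExpressionMatrix:
    """Subtract each sample's normalization factor from every miRNA (log scale).

    This is the log-space equivalent of dividing linear-scale values by the
    geometric mean of the reference panel; linear output is ``2**values``.
    """
    factor = normalization_factor(matrix, normalizers.mirna_ids)
    return ExpressionMatrix(matrix.values.sub(factor, axis=1), matrix.groups.copy())
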