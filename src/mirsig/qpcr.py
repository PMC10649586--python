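"""RT-qPCR relative quantification: replicate aggregation, 2^-dCq, 2^-ddCq.

Quantification cycles (Cq) sit on an inverted log2 scale: one cycle equals
one doubling, lower Cq means higher expression.  Relative expression of a
target against a reference panel is ``2**(-dCq)`` with
``dCq = Cq_target − Cq_ref``, where ``Cq_ref`` is the arithmetic mean of the
panel's Cq values (the geometric mean on the linear scale).  Group
fold-changes are ``2**(-ddCq)`` with ``ddCq = mean dCq(M) − mean dCq(B)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GROUP_BORDERLINE, GROUP_MALIGNANT, CqTable


@dataclass
class AggregatedCq:
    """Per (sample, miRNA) mean Cq with replicate QC.

    ``data`` columns: ``sample_id``, ``mirna_id``, ``cq_mean``, ``cq_sd``
    (NaN for single replicates), ``n_replicates``.  Missing reactions stay
    missing — they appear as absent rows, never imputed.
    """

    data: pd.DataFrame

    @property
    def wide(self) -> pd.DataFrame:
        """Mean Cq as miRNA x sample matrix (NaN where unmeasured)."""
        return self.data.pivot(index="mirna_id", columns="sample_id", values="cq_mean")


@dataclass
class RelativeExpression:
    """2^-dCq relative expression against a reference panel.

    ``delta_cq`` is a miRNA x sample matrix of ``Cq_target − Cq_ref``;
    ``ref_cq`` the per-sample reference Cq; ``normalizer_ids`` the panel.
    """

    delta_cq: pd.DataFrame
    ref_cq: pd.Series
    normalizer_ids: list[str]

    @property
    def linear(self) -> pd.DataFrame:
        """Linear-scale relative expression 2**(-dCq), > 0."""
        return 2.0 ** (-self.delta_cq)

    @property
    def log2(self) -> pd.DataFrame:
        """Log2 relative expression, i.e. −dCq."""
        return -self.delta_cq

    def group_summary(self, groups: pd.Series) -> pd.DataFrame:
        """Per miRNA x group mean and SEM of linear relative expression."""
        lin = self.linear
        groups = pd.Series(groups).loc[lin.columns]
        mean = lin.T.groupby(groups).mean().T
        sem = lin.T.groupby(groups).sem().T
        mean.columns = [f"mean_{g}" for g in mean.columns]
        sem.columns = [f"sem_{g}" for g in sem.columns]
        return pd.concat([mean, sem], axis=1)


def aggregate_replicates(raw: CqTable) -> AggregatedCq:
    """Arithmetic mean and SD of the available replicate Cqs.

    No outlier removal is applied; the SD column is reported for QC.  A
    single replicate yields its own value with an undefined (NaN) SD.
    """
    grouped = raw.data.groupby(["sample_id", "mirna_id"], sort=True)["cq"]
    agg = grouped.agg(cq_mean="mean", cq_sd="std", n_replicates="count").reset_index()
    return AggregatedCq(agg)


def delta_cq(cq: CqTable | AggregatedCq, normalizers: list[str]) -> RelativeExpression:
    """Relative expression 2^-dCq against the geometric-mean reference.

    ``Cq_ref`` per sample is the arithmetic mean of the normalizers' mean
    Cqs.  Samples missing any normalizer are excluded entirely (a partial
    reference would shift that sample against all others) with a warning.
    """
    if not normalizers:
        raise ValueError("need at least one normalizer")
    agg = aggregate_replicates(cq) if isinstance(cq, CqTable) else cq
    wide = agg.wide
    missing = [m for m in normalizers if m not in wide.index]
    if missing:
        raise KeyError(f"normalizers absent from Cq table: {missing}")
    ref_rows = wide.loc[list(normalizers)]
    usable = ref_rows.notna().all(axis=0)
    dropped = list(usable.index[~usable])
    if dropped:
        warnings.warn(
            f"samples missing a normalizer Cq excluded: {dropped}", stacklevel=2
        )
    wide = wide.loc[:, usable]
    ref = ref_rows.loc[:, usable].mean(axis=0).rename("ref_cq")
    targets = wide.drop(index=list(normalizers))
    return RelativeExpression(
        delta_cq=targets.sub(ref, axis=1),
        ref_cq=ref,
        normalizer_ids=list(normalizers),
    )


def delta_delta_cq(rel: RelativeExpression, groups: pd.Series) -> pd.DataFrame:
    """Per-miRNA ddCq and fold-change 2^-ddCq for M relative to B."""
    groups = pd.Series(groups).loc[rel.delta_cq.columns]
    for g in (GROUP_BORDERLINE, GROUP_MALIGNANT):
        if not (groups == g).any():
            raise ValueError(f"group {g!r} has no samples with defined values")
    mean_dcq = rel.delta_cq.T.groupby(groups).mean().T
    ddcq = mean_dcq[GROUP_MALIGNANT] - mean_dcq[GROUP_BORDERLINE]
    return pd.DataFrame(
        {"delta_delta_cq": ddcq, "fold_change": 2.0 ** (-ddcq)}
    ).rename_axis("mirna_id")


def differential_test(values: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """Pooled-variance two-sample t-test, two-sided (sign convention B − M).

    Degenerate inputs: zero pooled variance with equal means gives
    (t=0, p=1); zero pooled variance with unequal means gives (±inf, 0),
    flagged by the infinite statistic.
    """
    values = pd.Series(values).dropna()
    groups = pd.Series(groups).loc[values.index]
    b = values[groups == GROUP_BORDERLINE].to_numpy(dtype=float)
    m = values[groups == GROUP_MALIGNANT].to_numpy(dtype=float)
    if len(b) < 2 or len(m) < 2:
        raise ValueError("need >= 2 samples per group")
    if np.ptp(b) == 0 and np.ptp(m) == 0:
        if b[0] == m[0]:
            return 0.0, 1.0
        return (np.inf if b[0] > m[0] else -np.inf), 0.0
    t, p = stats.ttest_ind(b, m, equal_var=True)
    return float(t), float(p)


def differential_table(
    rel: RelativeExpression,
    groups: pd.Series,
    log_scale: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-miRNA fold-change and equal-variance t-test.

    Testing is on the log2 relative expression (−dCq) by default, where the
    equal-variance assumption is more defensible; set ``log_scale=False`` to
    test the linear 2^-dCq values instead.
    """
    groups = pd.Series(groups).loc[rel.delta_cq.columns]
    values = rel.log2 if log_scale else rel.linear
    fc = delta_delta_cq(rel, groups)
    stats_rows = {m: differential_test(values.loc[m], groups) for m in values.index}
    out = fc.copy()
    out["t"] = [stats_rows[m][0] for m in out.index]
    out["p"] = [stats_rows[m][1] for m in out.index]
    out["significant"] = out["p"] < alpha
    return out
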