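"""Two-step selection of differentially expressed miRNAs.

The funnel applied to a two-group log2 expression matrix:

1. **Stringent step** — mean expression above a detectability floor
   (default > 5 log2, in at least one group) and an absolute fold-change of
   at least a factor 2 (|log2 FC| >= 1), both directions.
2. **Fold-change-only step** — up-regulated miRNAs with fold-change strictly
   greater than the factor, with no expression floor, excluding miRNAs
   already selected.

Each candidate also carries the resubstitution error count of the best
single-threshold classifier on its own values, and boolean provenance flags
for the follow-up filters (expression rule, PCR-probe availability), so the
funnel can be audited rather than silently shrunk.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import GROUP_BORDERLINE, GROUP_MALIGNANT, CandidateSet, ExpressionMatrix

UP = "up"
DOWN = "down"


def log2_fold_change(matrix: ExpressionMatrix, mirna_id: str) -> float:
    """Log2 fold-change of M relative to B: mean_M − mean_B on the log2 scale.

    Equals log2 of the ratio of linear-scale geometric means.
    """
    if mirna_id not in matrix.values.index:
        raise KeyError(f"unknown miRNA id: {mirna_id}")
    means = matrix.group_means().loc[mirna_id]
    return float(means[GROUP_MALIGNANT] - means[GROUP_BORDERLINE])


def classification_errors(values: pd.Series, groups: pd.Series, direction: str = UP) -> int:
    """Minimum resubstitution errors of a single-threshold classifier.

    Orientation is fixed by ``direction``: ``up`` calls M when the value is
    strictly above the threshold, ``down`` when strictly below.  Thresholds
    are taken at midpoints of consecutive sorted unique values plus ±inf; a
    value equal to the threshold is classified on the B side.
    """
    values = pd.Series(values)
    groups = pd.Series(groups).loc[values.index]
    if not (groups == GROUP_BORDERLINE).any() or not (groups == GROUP_MALIGNANT).any():
        raise ValueError("both groups must be present")
    v = values.to_numpy(dtype=float)
    if direction == DOWN:
        v = -v
    elif direction != UP:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    is_m = (groups == GROUP_MALIGNANT).to_numpy()
    uniq = np.unique(v)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    # errors(t) = malignant samples at or below t + borderline samples above t
    errors = [(is_m & (v <= t)).sum() + (~is_m & (v > t)).sum() for t in thresholds]
    return int(min(errors))


def _candidate_rows(
    matrix: ExpressionMatrix, ids: list[str], direction_map: dict[str, str]
) -> pd.DataFrame:
    means = matrix.group_means()
    rows = []
    for m in ids:
        d = direction_map[m]
        rows.append(
            {
                "mirna_id": m,
                "direction": d,
                "mean_expr_B": means.loc[m, GROUP_BORDERLINE],
                "mean_expr_M": means.loc[m, GROUP_MALIGNANT],
                "log2_fold_change": means.loc[m, GROUP_MALIGNANT] - means.loc[m, GROUP_BORDERLINE],
                "n_errors": classification_errors(matrix.values.loc[m], matrix.groups, d),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "direction",
            "mean_expr_B",
            "mean_expr_M",
            "log2_fold_change",
            "n_errors",
        ],
    )
    df["perfect"] = df["n_errors"] == 0
    df["at_most_2_errors"] = df["n_errors"] <= 2
    return df


def select_stringent(
    matrix: ExpressionMatrix, expr_min: float = 5.0, min_factor: float = 2.0
) -> CandidateSet:
    """Stringent selection: |FC| >= factor and expression above the floor.

    Keeps miRNAs whose |log2 FC| >= log2(min_factor) (boundary included) and
    whose mean log2 expression exceeds ``expr_min`` in at least one group.
    """
    if min_factor <= 0:
        raise ValueError("min_factor must be positive")
    means = matrix.group_means()
    fc = means[GROUP_MALIGNANT] - means[GROUP_BORDERLINE]
    log2f = np.log2(min_factor)
    keep = (
        (fc.abs() >= log2f)
        & (fc != 0)
        & ((means[GROUP_BORDERLINE] > expr_min) | (means[GROUP_MALIGNANT] > expr_min))
    )
    ids = list(fc.index[keep])
    directions = {m: (UP if fc[m] > 0 else DOWN) for m in ids}
    df = _candidate_rows(matrix, ids, directions)
    df["stringent"] = True
    df["fc_only"] = False
    return CandidateSet(df)


def select_fc_only(
    matrix: ExpressionMatrix,
    min_factor: float = 2.0,
    direction: str = UP,
    exclude: CandidateSet | None = None,
) -> CandidateSet:
    """Fold-change-only selection (no expression floor), one direction.

    Keeps miRNAs with log2 FC strictly greater than log2(min_factor) (for
    ``up``; strictly less than −log2(min_factor) for ``down``), excluding any
    already in ``exclude``.
    """
    if min_factor <= 0:
        raise ValueError("min_factor must be positive")
    means = matrix.group_means()
    fc = means[GROUP_MALIGNANT] - means[GROUP_BORDERLINE]
    log2f = np.log2(min_factor)
    if direction == UP:
        keep = fc > log2f
    elif direction == DOWN:
        keep = fc < -log2f
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    excluded = set(exclude.mirna_ids) if exclude is not None else set()
    ids = [m for m in fc.index[keep] if m not in excluded]
    df = _candidate_rows(matrix, ids, {m: direction for m in ids})
    df["stringent"] = False
    df["fc_only"] = True
    return CandidateSet(df)


def combine_candidates(*sets: CandidateSet) -> CandidateSet:
    """Union of candidate sets; the first occurrence of an id wins."""
    tables = [s.table for s in sets if not s.table.empty]
    if not tables:
        return CandidateSet()
    df = pd.concat(tables, ignore_index=True)
    df = df.drop_duplicates(subset="mirna_id", keep="first").reset_index(drop=True)
    return CandidateSet(df)


def apply_expression_rule(
    candidates: CandidateSet,
    matrix: ExpressionMatrix,
    expr_B_min: float = 5.0,
    expr_M_min: float = 20.0,
) -> CandidateSet:
    """Flag candidates whose group-mean expression clears either group floor.

    The rule is an OR: mean B expression above ``expr_B_min`` or mean M
    expression above ``expr_M_min``.  The default M floor of 20 reproduces
    the published rule verbatim even though it exceeds plausible log2
    intensities; it is configurable for that reason.
    """
    df = candidates.table.copy()
    if df.empty:
        df["expression_rule"] = pd.Series(dtype=bool)
        return CandidateSet(df)
    means = matrix.group_means()
    df["expression_rule"] = [
        bool(
            means.loc[m, GROUP_BORDERLINE] > expr_B_min
            or means.loc[m, GROUP_MALIGNANT] > expr_M_min
        )
        for m in df["mirna_id"]
    ]
    return CandidateSet(df)


def filter_probe_available(candidates: CandidateSet, probe_list: set[str]) -> CandidateSet:
    """Flag candidates with an available PCR probe (id present in the list).

    Candidates are flagged, not dropped, so both views stay available; use
    ``.with_flag("probe_available")`` for the filtered view.
    """
    if not probe_list:
        warnings.warn("empty probe list: all candidates flagged unavailable", stacklevel=2)
    df = candidates.table.copy()
    if df.empty:
        df["probe_available"] = pd.Series(dtype=bool)
        return CandidateSet(df)
    df["probe_available"] = df["mirna_id"].isin(set(probe_list))
    return CandidateSet(df)
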