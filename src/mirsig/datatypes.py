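"""Core data containers shared across the pipeline.

The pipeline operates on two-group (borderline ``B`` vs malignant ``M``)
expression data in two physical forms: log2 microarray intensities and
RT-qPCR quantification cycles (Cq).  Both are held in thin dataclasses
wrapping :class:`pandas.DataFrame` so every stage can rely on validated
shape and labelling without re-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_BORDERLINE = "B"
GROUP_MALIGNANT = "M"


class ConfigurationError(ValueError):
    """Invalid parameter combination (overlapping gene sets, bad thresholds...)."""


@dataclass
class ExpressionMatrix:
    """Log2 expression intensities, miRNAs in rows, samples in columns.

    Parameters
    ----------
    values
        DataFrame of log2 intensities; index = miRNA ids, columns = sample ids.
    groups
        Series mapping each sample id to one of exactly two group labels
        (by convention ``"B"`` for borderline and ``"M"`` for malignant).
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.groups = pd.Series(self.groups)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate miRNA ids: {dup}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.groups = self.groups.loc[self.values.columns]
        labels = sorted(self.groups.unique())
        if len(labels) != 2:
            raise ValueError(f"expected exactly two group labels, got {labels}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group_labels(self) -> list[str]:
        return sorted(self.groups.unique())

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def group_means(self) -> pd.DataFrame:
        """Per-miRNA mean log2 expression for each group (columns = groups)."""
        return self.values.T.groupby(self.groups).mean().T

    def subset(self, mirna_ids: list[str]) -> "ExpressionMatrix":
        unknown = [m for m in mirna_ids if m not in self.values.index]
        if unknown:
            raise KeyError(f"unknown miRNA ids: {unknown}")
        return ExpressionMatrix(self.values.loc[mirna_ids].copy(), self.groups.copy())


@dataclass
class CqTable:
    """Replicate-level quantification cycles in long format.

    ``data`` columns: ``sample_id``, ``mirna_id``, ``replicate``, ``cq``.
    Missing reactions ("undetermined" wells) are simply absent rows, never
    zeros or sentinel cycle values.
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "mirna_id", "replicate", "cq")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"Cq table missing columns: {missing}")
        cq = self.data["cq"].to_numpy(dtype=float)
        if not np.isfinite(cq).all():
            raise ValueError("Cq values must be finite; drop undetermined wells instead")
        if (cq <= 0).any():
            raise ValueError("Cq values must be > 0")

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())

    @property
    def mirna_ids(self) -> list[str]:
        return sorted(self.data["mirna_id"].unique())


@dataclass
class SimulatedStudy:
    """A simulated two-group study with its ground truth.

    ``effects`` maps miRNA id -> planted log2 group effect (M minus B);
    ``normalizer_ids`` are the planted stable reference miRNAs;
    ``sample_offsets`` are the per-sample additive log2 shifts shared between
    the microarray and qPCR views of the same virtual sample.
    """

    expression: ExpressionMatrix
    effects: dict[str, float]
    normalizer_ids: list[str]
    sample_offsets: pd.Series
    baselines: pd.Series
    seed: int
    cq: CqTable | None = None

    @property
    def up_ids(self) -> list[str]:
        return [m for m, d in self.effects.items() if d > 0]

    @property
    def down_ids(self) -> list[str]:
        return [m for m, d in self.effects.items() if d < 0]


@dataclass
class CandidateSet:
    """Differential-expression candidates with filter provenance.

    ``table`` columns: ``mirna_id``, ``direction`` (up/down, M relative to B),
    ``mean_expr_B``, ``mean_expr_M``, ``log2_fold_change``, ``n_errors`` and one
    boolean column per applied filter (``stringent``, ``fc_only``, ``perfect``,
    ``at_most_2_errors``, ``expression_rule``, ``probe_available``).
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def mirna_ids(self) -> list[str]:
        if self.table.empty:
            return []
        return list(self.table["mirna_id"])

    def with_flag(self, flag: str) -> "CandidateSet":
        if self.table.empty or flag not in self.table.columns:
            return CandidateSet(self.table.iloc[0:0].copy())
        return CandidateSet(self.table[self.table[flag].fillna(False)].reset_index(drop=True))

    def ids_by_direction(self, direction: str) -> list[str]:
        if self.table.empty:
            return []
        return list(self.table.loc[self.table["direction"] == direction, "mirna_id"])

    def __len__(self) -> int:
        return len(self.table)
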