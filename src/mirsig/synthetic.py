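"""Two-group synthetic miRNA studies with known ground truth.

The generator emulates the statistical structure of a borderline-vs-malignant
FFPE miRNA study: RMA-like log2 microarray intensities and RT-qPCR Cq
triplicates for the same virtual samples.

Model
-----
Log2 intensity of miRNA *i* in sample *j*::

    x_ij = mu_i + delta_i * 1[group(j) = M] + s_j + eps_ij

with baseline ``mu_i`` drawn uniformly on a log2 range, a planted group
effect ``delta_i`` (zero except for the designated up/down-regulated
miRNAs), a per-sample additive offset ``s_j ~ N(0, sample_offset_sd^2)``
standing in for RNA amount / labelling variation, and measurement noise
``eps_ij ~ N(0, noise_sd^2)`` (a smaller SD for the planted normalizers,
which is what makes them stable).

The qPCR view maps the same latent expression to quantification cycles with
slope −1 (perfect doubling per cycle)::

    Cq_ijr = intercept − (mu_i + delta_i * 1[M] + s_j) + eta_ijr

so one log2 unit of expression is one cycle, and the per-sample offset
``s_j`` is shared between the two views — the property that lets ratio
analysis cancel it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    GROUP_BORDERLINE,
    GROUP_MALIGNANT,
    ConfigurationError,
    CqTable,
    ExpressionMatrix,
    SimulatedStudy,
)


@dataclass(frozen=True)
class GroupDesign:
    """Sample layout of a two-group study (defaults: 11 B vs 12 M)."""

    n_borderline: int = 11
    n_malignant: int = 12

    def __post_init__(self) -> None:
        if self.n_borderline < 2 or self.n_malignant < 2:
            raise ConfigurationError("each group needs at least 2 samples")

    @property
    def sample_ids(self) -> list[str]:
        return [f"B{i + 1:02d}" for i in range(self.n_borderline)] + [
            f"M{i + 1:02d}" for i in range(self.n_malignant)
        ]

    @property
    def groups(self) -> pd.Series:
        labels = [GROUP_BORDERLINE] * self.n_borderline + [GROUP_MALIGNANT] * self.n_malignant
        return pd.Series(labels, index=self.sample_ids, name="group")

    @property
    def n_samples(self) -> int:
        return self.n_borderline + self.n_malignant


@dataclass
class SimParams:
    """Ground-truth parameters of a simulated study.

    ``de_up`` / ``de_down`` map miRNA id to the planted log2 effect (M minus
    B; positive for up, negative for down).  ``normalizer_ids`` are stable
    reference miRNAs: zero group effect and ``noise_sd_normalizer`` measurement
    noise.  Baselines of signal genes (DE + normalizers) are drawn from
    ``de_baseline_range`` so they sit above the detectability filter, as real
    validated candidates do; background genes straddle it.
    """

    n_mirnas: int = 1000
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    de_baseline_range: tuple[float, float] = (6.0, 12.0)
    noise_sd: float = 0.5
    de_up: dict[str, float] = field(default_factory=dict)
    de_down: dict[str, float] = field(default_factory=dict)
    normalizer_ids: list[str] = field(default_factory=list)
    noise_sd_normalizer: float = 0.1
    sample_offset_sd: float = 0.5
    cq_intercept: float = 30.0
    replicate_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        up, down, norm = set(self.de_up), set(self.de_down), set(self.normalizer_ids)
        overlap = (up & down) | (up & norm) | (down & norm)
        if overlap:
            raise ConfigurationError(
                f"DE and normalizer sets must be disjoint; overlap: {sorted(overlap)}"
            )
        if any(d <= 0 for d in self.de_up.values()):
            raise ConfigurationError("de_up effects must be > 0")
        if any(d >= 0 for d in self.de_down.values()):
            raise ConfigurationError("de_down effects must be < 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.noise_sd_normalizer > self.noise_sd:
            raise ConfigurationError("normalizer noise must not exceed noise_sd")
        if self.replicate_sd < 0:
            raise ConfigurationError("replicate_sd must be >= 0")
        n_signal = len(up) + len(down) + len(norm)
        if n_signal > self.n_mirnas:
            raise ConfigurationError("more designated miRNAs than n_mirnas")

    @property
    def effects(self) -> dict[str, float]:
        return {**self.de_up, **self.de_down}

    @property
    def mirna_ids(self) -> list[str]:
        signal = list(self.de_up) + list(self.de_down) + list(self.normalizer_ids)
        n_bg = self.n_mirnas - len(signal)
        return signal + [f"miR-bg-{i + 1:04d}" for i in range(n_bg)]


def default_study_params(seed: int = 0, **overrides) -> SimParams:
    """Parameters mirroring the study design: 5 up- and 10 down-regulated
    miRNAs at |log2 effect| = 2, five stable normalizers."""
    params = dict(
        de_up={f"miR-up-{i + 1:02d}": 2.0 for i in range(5)},
        de_down={f"miR-dn-{i + 1:02d}": -2.0 for i in range(10)},
        normalizer_ids=[f"miR-norm-{i + 1:02d}" for i in range(5)],
        seed=seed,
    )
    params.update(overrides)
    return SimParams(**params)


def _latent(design: GroupDesign, params: SimParams):
    """Baselines, per-sample offsets and noise streams, reproducibly.

    The shared stream (baselines + offsets) is consumed identically by the
    microarray and qPCR views so both describe the same virtual samples.
    """
    ss_shared, ss_array, ss_qpcr = np.random.SeedSequence(params.seed).spawn(3)
    rng = np.random.default_rng(ss_shared)
    ids = params.mirna_ids
    lo, hi = params.baseline_mean_range
    baselines = pd.Series(rng.uniform(lo, hi, size=len(ids)), index=ids)
    dlo, dhi = params.de_baseline_range
    signal_ids = list(params.effects) + list(params.normalizer_ids)
    baselines.loc[signal_ids] = rng.uniform(dlo, dhi, size=len(signal_ids))
    offsets = pd.Series(
        rng.normal(0.0, params.sample_offset_sd, size=design.n_samples),
        index=design.sample_ids,
    )
    return baselines, offsets, ss_array, ss_qpcr


def _mean_matrix(design: GroupDesign, params: SimParams, baselines: pd.Series, offsets: pd.Series):
    ids = params.mirna_ids
    is_m = (design.groups == GROUP_MALIGNANT).to_numpy(dtype=float)
    delta = np.array([params.effects.get(m, 0.0) for m in ids])
    return baselines.to_numpy()[:, None] + np.outer(delta, is_m) + offsets.to_numpy()[None, :]


def simulate_microarray(design: GroupDesign, params: SimParams) -> SimulatedStudy:
    """Simulate the log2 microarray view; ground truth travels with it."""
    baselines, offsets, ss_array, _ = _latent(design, params)
    rng = np.random.default_rng(ss_array)
    ids = params.mirna_ids
    mean = _mean_matrix(design, params, baselines, offsets)
    sd = np.full(len(ids), params.noise_sd)
    norm_pos = [ids.index(m) for m in params.normalizer_ids]
    sd[norm_pos] = params.noise_sd_normalizer
    values = mean + rng.normal(0.0, 1.0, size=mean.shape) * sd[:, None]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=ids, columns=design.sample_ids), design.groups
    )
    return SimulatedStudy(
        expression=matrix,
        effects=dict(params.effects),
        normalizer_ids=list(params.normalizer_ids),
        sample_offsets=offsets,
        baselines=baselines,
        seed=params.seed,
    )


def simulate_qpcr(
    design: GroupDesign,
    params: SimParams,
    mirna_subset: list[str],
    n_replicates: int = 3,
) -> CqTable:
    """Simulate Cq triplicates for a subset of miRNAs of the same study.

    Cq is the latent log2 expression mapped through an affine slope −1:
    higher expression, lower Cq, one cycle per log2 unit.
    """
    if not mirna_subset:
        raise ValueError("mirna_subset must be non-empty")
    ids = params.mirna_ids
    unknown = [m for m in mirna_subset if m not in ids]
    if unknown:
        raise KeyError(f"miRNAs not in simulated ground truth: {unknown}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    baselines, offsets, _, ss_qpcr = _latent(design, params)
    rng = np.random.default_rng(ss_qpcr)
    is_m = (design.groups == GROUP_MALIGNANT).to_numpy(dtype=float)
    records = []
    for mirna in mirna_subset:
        latent = baselines[mirna] + params.effects.get(mirna, 0.0) * is_m + offsets.to_numpy()
        cq_mean = params.cq_intercept - latent
        noise = rng.normal(0.0, params.replicate_sd, size=(design.n_samples, n_replicates))
        for j, sample in enumerate(design.sample_ids):
            for r in range(n_replicates):
                records.append((sample, mirna, r + 1, cq_mean[j] + noise[j, r]))
    return CqTable(pd.DataFrame(records, columns=["sample_id", "mirna_id", "replicate", "cq"]))


def simulate_study(
    design: GroupDesign,
    params: SimParams,
    qpcr_subset: list[str] | None = None,
    n_replicates: int = 3,
) -> SimulatedStudy:
    """Microarray plus qPCR views of one virtual cohort.

    By default the qPCR panel is the designated signal set (DE miRNAs and
    normalizers), mirroring a validation experiment.
    """
    study = simulate_microarray(design, params)
    if qpcr_subset is None:
        qpcr_subset = list(params.effects) + list(params.normalizer_ids)
    study.cq = simulate_qpcr(design, params, qpcr_subset, n_replicates=n_replicates)
    return study
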