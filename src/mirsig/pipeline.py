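"""End-to-end orchestration: selection → normalizers → quantification →
ratios → double ratios, with a reproducible report.

The pipeline consumes either files (expression TSV + groups TSV, optionally
a Cq TSV and a probe list) or a simulated study, applies each stage with
the configured thresholds, and emits a report carrying every intermediate
table plus the selection-funnel counts, so the whole analysis can be
audited from one object.  Identical config + seed gives identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

import mirsig

from . import double_ratio as dr
from . import io, normfinder, qpcr, ratios, selection
from .datatypes import CandidateSet, ExpressionMatrix
from .synthetic import GroupDesign, SimParams, default_study_params, simulate_study


@dataclass
class PipelineConfig:
    """All stage parameters and file paths in one place.

    Defaults are the published operating points: expression floor 5 (log2),
    fold-change factor 2, stability bound 0.25, three normalizers, alpha
    0.05, four distinct miRNAs per admissible pair.
    """

    # inputs (ignored when simulate=True)
    expression_path: str | None = None
    groups_path: str | None = None
    cq_path: str | None = None
    probes_path: str | None = None
    # simulation
    simulate: bool = False
    n_borderline: int = 11
    n_malignant: int = 12
    seed: int = 0
    # stage parameters
    expr_min: float = 5.0
    min_factor: float = 2.0
    expr_B_min: float = 5.0
    expr_M_min: float = 20.0
    stability_max: float = 0.25
    n_normalizers: int = 3
    alpha: float = 0.05
    rule: str = "and"
    min_distinct: int = 4
    # explicit up/down panels (otherwise derived from the candidate funnel)
    up_ids: list[str] = field(default_factory=list)
    down_ids: list[str] = field(default_factory=list)
    normalizer_ids: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        design = GroupDesign(config.n_borderline, config.n_malignant)
        params = default_study_params(seed=config.seed)
        study = simulate_study(design, params)
        probes = None if config.probes_path is None else io.read_probe_list(config.probes_path)
        return study.expression, study.cq, probes, study
    if not config.expression_path or not config.groups_path:
        raise ValueError("need expression_path and groups_path (or simulate=True)")
    groups = io.read_groups_tsv(config.groups_path)
    matrix = io.read_expression_tsv(config.expression_path, groups)
    cq = None if config.cq_path is None else io.read_cq_tsv(config.cq_path)
    probes = None if config.probes_path is None else io.read_probe_list(config.probes_path)
    return matrix, cq, probes, None


def _funnel(matrix: ExpressionMatrix, probes, config: PipelineConfig):
    stringent = selection.select_stringent(matrix, config.expr_min, config.min_factor)
    fc_only = selection.select_fc_only(matrix, config.min_factor, exclude=stringent)
    candidates = selection.combine_candidates(stringent, fc_only)
    candidates = selection.apply_expression_rule(
        candidates, matrix, config.expr_B_min, config.expr_M_min
    )
    if probes is not None:
        candidates = selection.filter_probe_available(candidates, probes)
    counts = {
        "stringent_total": len(stringent),
        "stringent_up": len(stringent.ids_by_direction("up")),
        "stringent_down": len(stringent.ids_by_direction("down")),
        "fc_only_up": len(fc_only),
        "combined": len(candidates),
        "perfect": int(candidates.table["perfect"].sum()) if len(candidates) else 0,
        "at_most_2_errors": int(candidates.table["at_most_2_errors"].sum())
        if len(candidates)
        else 0,
    }
    if probes is not None and len(candidates):
        counts["probe_available"] = int(candidates.table["probe_available"].sum())
    return candidates, counts


def _panels(candidates: CandidateSet, config: PipelineConfig, probes) -> tuple[list[str], list[str]]:
    if config.up_ids and config.down_ids:
        return list(config.up_ids), list(config.down_ids)
    usable = candidates.with_flag("probe_available") if probes is not None else candidates
    return usable.ids_by_direction("up"), usable.ids_by_direction("down")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the report bundle as a dict.

    Keys: ``config``, ``funnel``, ``candidates``, ``stability``,
    ``normalizers``, ``relative_expression``, ``ratio_summary``,
    ``pair_errors``, ``perfect_pairs`` plus scalar counts.  DataFrames stay
    DataFrames; use :func:`write_report` to serialize.
    """
    matrix, cq, probes, study = _load_inputs(config)

    candidates, funnel_counts = _funnel(matrix, probes, config)

    stab = normfinder.stability_values(matrix)
    if config.normalizer_ids:
        norm_set = normfinder.NormalizerSet(
            mirna_ids=list(config.normalizer_ids),
            factors=normfinder.normalization_factor(matrix, list(config.normalizer_ids)),
        )
    else:
        norm_set = normfinder.select_normalizers(
            stab,
            matrix,
            expr_min=config.expr_min,
            stability_max=config.stability_max,
            k=config.n_normalizers,
            probe_list=probes,
        )
    normalized = normfinder.normalize(matrix, norm_set)

    up_ids, down_ids = _panels(candidates, config, probes)
    if not up_ids or not down_ids:
        raise ValueError(
            f"cannot build ratios: {len(up_ids)} up and {len(down_ids)} down miRNAs selected"
        )

    if cq is not None:
        agg = qpcr.aggregate_replicates(cq)
        rel = qpcr.delta_cq(agg, norm_set.mirna_ids)
        diff = qpcr.differential_table(rel, matrix.groups, alpha=config.alpha)
        ratio_input = rel
        # the validation panel: only candidates actually measured by qPCR
        measured = set(rel.linear.index)
        up_ids = [m for m in up_ids if m in measured]
        down_ids = [m for m in down_ids if m in measured]
        if not up_ids or not down_ids:
            raise ValueError("no selected up/down miRNAs were measured by qPCR")
    else:
        agg, rel, diff = None, None, None
        # normalized log2 intensities stand in for -dCq: same scale, same model
        ratio_input = 2.0**normalized.values

    ratio_matrix = ratios.build_ratios(ratio_input, up_ids, down_ids)
    ratio_summary = ratios.summarize_ratios(ratio_matrix, matrix.groups, alpha=config.alpha)

    pair_errors = dr.error_matrix(
        ratio_matrix, matrix.groups, rule=config.rule, min_distinct=config.min_distinct
    )
    perfect, perfect_fraction = dr.perfect_pairs(pair_errors)

    return {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "versions": {
            "mirsig": mirsig.__version__,
            "pandas": pd.__version__,
        },
        "funnel": funnel_counts,
        "candidates": candidates.table,
        "stability": pd.DataFrame({"rho": stab.rho, "mean_expr": stab.mean_expr}),
        "tau2": stab.tau2,
        "normalizers": norm_set.mirna_ids,
        "aggregated_cq": None if agg is None else agg.data,
        "relative_expression": None if rel is None else rel.linear,
        "differential": diff,
        "ratios": ratio_matrix.values,
        "ratio_summary": ratio_summary,
        "n_ratios": len(ratio_matrix.values),
        "n_significant_ratios": int(ratio_summary["significant"].sum()),
        "pair_errors": pair_errors.pairs,
        "n_admissible_pairs": len(pair_errors.pairs),
        "perfect_pairs": perfect,
        "n_perfect_pairs": len(perfect),
        "perfect_fraction": perfect_fraction,
        "rule": pair_errors.rule,
        "ground_truth": None
        if study is None
        else {"effects": study.effects, "normalizer_ids": study.normalizer_ids},
    }


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write the report bundle: one TSV per table plus report.json.

    The JSON carries the scalar summary (funnel counts, pair statistics,
    config and its hash); no timestamps, so a rerun with the same config and
    seed is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "candidates": report["candidates"],
        "stability": report["stability"],
        "ratios": report["ratios"],
        "ratio_summary": report["ratio_summary"],
        "pair_errors": report["pair_errors"],
        "perfect_pairs": report["perfect_pairs"],
    }
    for name in ("aggregated_cq", "relative_expression", "differential"):
        if report[name] is not None:
            tables[name] = report[name]
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t")
    scalars = {
        k: report[k]
        for k in (
            "config",
            "config_hash",
            "versions",
            "funnel",
            "tau2",
            "normalizers",
            "n_ratios",
            "n_significant_ratios",
            "n_admissible_pairs",
            "n_perfect_pairs",
            "perfect_fraction",
            "rule",
            "ground_truth",
        )
    }
    (out / "report.json").write_text(json.dumps(scalars, indent=2, sort_keys=True) + "\n")
    return out / "report.json"
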