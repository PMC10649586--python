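"""Differential candidate selection: fold-change semantics, the two-step
funnel, threshold-classifier error counts and the follow-up filters."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from mirsig import (
    apply_expression_rule,
    classification_errors,
    combine_candidates,
    filter_probe_available,
    log2_fold_change,
    select_fc_only,
    select_stringent,
)


def errors_brute_force(values, groups, direction):
    """Independent oracle: try a threshold in every gap of the sorted values."""
    v = np.asarray(values, dtype=float)
    if direction == "down":
        v = -v
    is_m = np.asarray(groups) == "M"
    candidates = np.concatenate(([v.min() - 1], np.sort(v), [v.max() + 1]))
    best = len(v)
    for t in candidates:
        errs = np.sum(is_m & (v <= t)) + np.sum(~is_m & (v > t))
        best = min(best, errs)
    return int(best)


class TestLog2FoldChange:
    def test_one_log2_unit(self):
        m = make_matrix({"g": [6, 6, 6, 7, 7, 7]}, 3, 3)
        assert log2_fold_change(m, "g") == pytest.approx(1.0)

    def test_identical_groups_zero(self):
        m = make_matrix({"g": [5, 6, 7, 5, 6, 7]}, 3, 3)
        assert log2_fold_change(m, "g") == pytest.approx(0.0)

    def test_toy_matrix_hand_value(self, toy_matrix):
        # B mean 5, M mean 9
        assert log2_fold_change(toy_matrix, "gene-a") == pytest.approx(4.0)

    def test_unknown_id(self, toy_matrix):
        with pytest.raises(KeyError):
            log2_fold_change(toy_matrix, "nope")


class TestClassificationErrors:
    def test_perfect_separation(self):
        v = pd.Series([1, 2, 3, 4, 5, 6], index=list("abcdef"))
        g = pd.Series(["B"] * 3 + ["M"] * 3, index=list("abcdef"))
        assert classification_errors(v, g, "up") == 0

    def test_interleaved_one_error(self):
        v = pd.Series([1, 4, 2, 5], index=list("abcd"))
        g = pd.Series(["B", "B", "M", "M"], index=list("abcd"))
        assert classification_errors(v, g, "up") == 1

    def test_constant_values_min_group_size(self):
        v = pd.Series([3.0] * 6, index=list("abcdef"))
        g = pd.Series(["B"] * 3 + ["M"] * 3, index=list("abcdef"))
        assert classification_errors(v, g, "up") == 3

    def test_down_orientation(self):
        v = pd.Series([6, 5, 4, 1, 2, 3], index=list("abcdef"))
        g = pd.Series(["B"] * 3 + ["M"] * 3, index=list("abcdef"))
        assert classification_errors(v, g, "down") == 0
        assert classification_errors(v, g, "up") == 3

    @pytest.mark.parametrize("direction", ["up", "down"])
    def test_matches_brute_force(self, rng, direction):
        """Midpoint-grid minimum equals an exhaustive scan over all gaps."""
        for _ in range(200):
            n_b, n_m = rng.integers(1, 7, size=2)
            idx = [f"s{i}" for i in range(n_b + n_m)]
            v = pd.Series(np.round(rng.normal(size=n_b + n_m), 1), index=idx)
            g = pd.Series(["B"] * n_b + ["M"] * n_m, index=idx)
            assert classification_errors(v, g, direction) == errors_brute_force(v, g, direction)


class TestStringent:
    def test_boundary_factor_two_kept(self):
        m = make_matrix({"g": [6, 6, 6, 7, 7, 7], "bg": [8, 8, 8, 8, 8, 8]}, 3, 3)
        cand = select_stringent(m)
        assert cand.mirna_ids == ["g"]
        assert cand.table.loc[0, "direction"] == "up"

    def test_low_expression_excluded(self):
        m = make_matrix({"g": [3, 3, 3, 4.5, 4.5, 4.5], "bg": [8, 8, 8, 8, 8, 8]}, 3, 3)
        assert select_stringent(m).mirna_ids == []

    def test_expression_floor_is_either_group(self):
        # B below, M above the floor: kept via the OR reading
        m = make_matrix({"g": [4, 4, 4, 6, 6, 6], "bg": [8, 8, 8, 8, 8, 8]}, 3, 3)
        assert select_stringent(m).mirna_ids == ["g"]

    def test_monotone_in_min_factor(self, rng):
        values = {f"g{i}": rng.uniform(2, 12, size=8).tolist() for i in range(30)}
        m = make_matrix(values, 4, 4)
        previous = None
        for factor in (1.0, 1.5, 2.0, 3.0, 5.0):
            ids = set(select_stringent(m, expr_min=-np.inf, min_factor=factor).mirna_ids)
            if previous is not None:
                assert ids <= previous
            previous = ids

    def test_factor_one_returns_all_nonzero_fc(self, rng):
        values = {f"g{i}": rng.uniform(2, 12, size=8).tolist() for i in range(20)}
        m = make_matrix(values, 4, 4)
        means = m.group_means()
        nonzero = set(means.index[(means["M"] - means["B"]) != 0])
        got = set(select_stringent(m, expr_min=-np.inf, min_factor=1.0).mirna_ids)
        assert got == nonzero

    def test_nonpositive_factor_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            select_stringent(toy_matrix, min_factor=0)


class TestFcOnly:
    def test_no_expression_floor(self):
        m = make_matrix({"g": [2, 2, 2, 3.5, 3.5, 3.5], "bg": [8, 8, 8, 8, 8, 8]}, 3, 3)
        assert select_fc_only(m).mirna_ids == ["g"]

    def test_boundary_excluded(self):
        # FC exactly 1 log2: stringent keeps it (>=), fc-only does not (>)
        m = make_matrix({"g": [6, 6, 6, 7, 7, 7], "bg": [8, 8, 8, 8, 8, 8]}, 3, 3)
        assert select_fc_only(m).mirna_ids == []

    def test_stringent_not_duplicated(self):
        m = make_matrix({"g": [6, 6, 6, 8, 8, 8], "bg": [8, 8, 8, 8, 8, 8]}, 3, 3)
        stringent = select_stringent(m)
        assert "g" in stringent.mirna_ids
        assert select_fc_only(m, exclude=stringent).mirna_ids == []

    def test_combined_funnel_counts(self):
        m = make_matrix(
            {
                "strong-up": [6, 6, 6, 8, 8, 8],  # stringent, up
                "strong-dn": [8, 8, 8, 6, 6, 6],  # stringent, down
                "faint-up": [2, 2, 2, 4, 4, 4],  # fc-only (below floor)
                "null": [7, 7, 7, 7, 7, 7],
            },
            3,
            3,
        )
        stringent = select_stringent(m)
        fc_only = select_fc_only(m, exclude=stringent)
        combined = combine_candidates(stringent, fc_only)
        assert set(stringent.mirna_ids) == {"strong-up", "strong-dn"}
        assert fc_only.mirna_ids == ["faint-up"]
        assert len(combined) == 3
        assert combined.table["mirna_id"].is_unique


class TestFollowUpFilters:
    @pytest.fixture
    def candidates(self):
        m = make_matrix(
            {
                "hi-b": [6, 6, 6, 8, 8, 8],
                "hi-m": [4, 4, 4, 21, 21, 21],
                "lo": [4, 4, 4, 10, 10, 10],
            },
            3,
            3,
        )
        return select_stringent(m, expr_min=-np.inf), m

    def test_expression_rule_branches(self, candidates):
        cand, m = candidates
        flagged = apply_expression_rule(cand, m)
        by_id = flagged.table.set_index("mirna_id")["expression_rule"]
        assert bool(by_id["hi-b"])  # passes via B branch
        assert bool(by_id["hi-m"])  # passes via M branch
        assert not bool(by_id["lo"])  # fails both

    def test_probe_filter_counts(self, candidates):
        cand, _ = candidates
        flagged = filter_probe_available(cand, {"hi-b", "hi-m"})
        assert set(flagged.with_flag("probe_available").mirna_ids) == {"hi-b", "hi-m"}

    def test_empty_probe_list_warns_and_retains_none(self, candidates):
        cand, _ = candidates
        with pytest.warns(UserWarning, match="empty probe list"):
            flagged = filter_probe_available(cand, set())
        assert flagged.with_flag("probe_available").mirna_ids == []

    def test_probe_superset_retains_all(self, candidates):
        cand, _ = candidates
        flagged = filter_probe_available(cand, {"hi-b", "hi-m", "lo", "extra"})
        assert len(flagged.with_flag("probe_available")) == len(cand)
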