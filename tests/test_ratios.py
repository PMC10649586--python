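"""Ratio construction and ROC/Youden scoring, checked against independent
rank-statistic and exhaustive-scan oracles."""

import numpy as np
import pandas as pd
import pytest

from mirsig import RatioMatrix, build_ratios, roc, summarize_ratios, youden_optimal
from mirsig.ratios import test_ratios as ratio_tests


def auc_pairwise(values, groups):
    """Oracle: fraction of (M, B) pairs ranked correctly, ties half."""
    v = pd.Series(values)
    g = pd.Series(groups).loc[v.index]
    m = v[g == "M"].to_numpy()
    b = v[g == "B"].to_numpy()
    total = 0.0
    for vm in m:
        for vb in b:
            total += 1.0 if vm > vb else (0.5 if vm == vb else 0.0)
    return total / (len(m) * len(b))


def youden_scan(values, groups):
    """Oracle: exhaustive scan of sensitivity + specificity − 1 over every
    threshold position between sorted values."""
    v = pd.Series(values).to_numpy(dtype=float)
    is_m = (pd.Series(groups).to_numpy() == "M")
    candidates = np.concatenate(([-np.inf], np.sort(np.unique(v)), [np.inf]))
    best = -2.0
    for t in candidates:
        sens = (is_m & (v > t)).sum() / is_m.sum()
        spec = (~is_m & (v <= t)).sum() / (~is_m).sum()
        best = max(best, sens + spec - 1.0)
    return best


def random_instance(rng, max_n=12, ties=True):
    n_b, n_m = rng.integers(1, max_n // 2 + 1, size=2)
    idx = [f"s{i}" for i in range(n_b + n_m)]
    raw = rng.normal(size=n_b + n_m)
    if ties:
        raw = np.round(raw, 1)  # provoke tied values
    values = pd.Series(raw, index=idx)
    groups = pd.Series(["B"] * n_b + ["M"] * n_m, index=idx)
    return values, groups


class TestBuildRatios:
    def make_linear(self, rng, mirnas, samples=6):
        cols = [f"s{i}" for i in range(samples)]
        return pd.DataFrame(
            rng.uniform(0.1, 10, size=(len(mirnas), samples)), index=mirnas, columns=cols
        )

    def test_five_by_ten_gives_fifty(self, rng):
        up = [f"u{i}" for i in range(5)]
        down = [f"d{i}" for i in range(10)]
        rm = build_ratios(self.make_linear(rng, up + down), up, down)
        assert len(rm.values) == 50
        assert rm.members("u0/d3") == ("u0", "d3")

    def test_single_pair_elementwise_quotient(self, rng):
        lin = self.make_linear(rng, ["u", "d"])
        rm = build_ratios(lin, ["u"], ["d"])
        np.testing.assert_allclose(rm.values.loc["u/d"], lin.loc["u"] / lin.loc["d"])

    def test_reference_cancels(self, rng):
        """Ratios from normalized values equal ratios from raw Cq values."""
        lin = self.make_linear(rng, ["u", "d"])
        factor = rng.uniform(0.5, 2.0, size=lin.shape[1])
        normalized = lin / factor
        raw = build_ratios(lin, ["u"], ["d"]).values
        norm = build_ratios(normalized, ["u"], ["d"]).values
        np.testing.assert_allclose(raw, norm, rtol=1e-12)

    def test_overlap_rejected(self, rng):
        lin = self.make_linear(rng, ["a", "b"])
        with pytest.raises(ValueError, match="overlap"):
            build_ratios(lin, ["a"], ["a", "b"])

    def test_missing_value_propagates(self, rng):
        lin = self.make_linear(rng, ["u", "d"])
        lin.loc["u", "s2"] = np.nan
        rm = build_ratios(lin, ["u"], ["d"])
        assert np.isnan(rm.values.loc["u/d", "s2"])


class TestRoc:
    def test_perfect_separation(self):
        v = pd.Series([1, 2, 3, 10, 11, 12], index=list("abcdef"), dtype=float)
        g = pd.Series(["B"] * 3 + ["M"] * 3, index=v.index)
        result = roc(v, g)
        assert result.auc == pytest.approx(1.0)
        perfect = (result.sensitivity == 1) & (result.specificity == 1)
        assert perfect.any()

    def test_identical_multisets_half(self):
        v = pd.Series([1, 2, 3, 1, 2, 3], index=list("abcdef"), dtype=float)
        g = pd.Series(["B"] * 3 + ["M"] * 3, index=v.index)
        assert roc(v, g).auc == pytest.approx(0.5)

    def test_trapezoid_equals_pairwise_oracle(self, rng):
        for _ in range(300):
            v, g = random_instance(rng)
            assert roc(v, g).auc == pytest.approx(auc_pairwise(v, g), abs=1e-12)

    def test_matches_sklearn(self, rng):
        """Independent library cross-check of the AUC."""
        from sklearn.metrics import roc_auc_score

        for _ in range(50):
            v, g = random_instance(rng)
            expected = roc_auc_score((g == "M").astype(int), v)
            assert roc(v, g).auc == pytest.approx(expected, abs=1e-12)

    def test_orientation_duality(self, rng):
        for _ in range(50):
            v, g = random_instance(rng)
            assert roc(v, g).auc + roc(-v, g).auc == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        for _ in range(50):
            v, g = random_instance(rng)
            assert roc(np.exp(v), g).auc == pytest.approx(roc(v, g).auc, abs=1e-12)

    def test_empty_group_rejected(self):
        v = pd.Series([1.0, 2.0], index=["a", "b"])
        g = pd.Series(["M", "M"], index=v.index)
        with pytest.raises(ValueError):
            roc(v, g)


class TestYouden:
    def test_perfect_separation_j_one(self):
        v = pd.Series([1, 2, 3, 10, 11, 12], index=list("abcdef"), dtype=float)
        g = pd.Series(["B"] * 3 + ["M"] * 3, index=v.index)
        _, j, sens, spec = youden_optimal(roc(v, g))
        assert (j, sens, spec) == (1.0, 1.0, 1.0)

    def test_constant_values_j_zero_at_infinite_threshold(self):
        v = pd.Series([2.0] * 6, index=list("abcdef"))
        g = pd.Series(["B"] * 3 + ["M"] * 3, index=v.index)
        thr, j, _, spec = youden_optimal(roc(v, g))
        assert j == 0.0
        assert np.isinf(thr)
        assert spec == 1.0  # tie broken toward specificity

    def test_sens_spec_arithmetic(self):
        """Sens 0.67 with spec 1.00 gives J = 0.67: two of three malignant
        samples above every borderline value."""
        v = pd.Series([1, 2, 3, 2.5, 10, 11], index=list("abcdef"), dtype=float)
        g = pd.Series(["B"] * 3 + ["M"] * 3, index=v.index)
        _, j, sens, spec = youden_optimal(roc(v, g))
        assert sens == pytest.approx(2 / 3)
        assert spec == pytest.approx(1.0)
        assert j == pytest.approx(2 / 3)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(300):
            v, g = random_instance(rng)
            _, j, _, _ = youden_optimal(roc(v, g))
            assert j == pytest.approx(youden_scan(v, g), abs=1e-12)


class TestTestRatios:
    def build(self, rng, up_shift):
        idx = [f"b{i}" for i in range(6)] + [f"m{i}" for i in range(6)]
        groups = pd.Series(["B"] * 6 + ["M"] * 6, index=idx)
        u = np.concatenate([rng.normal(3, 0.3, 6), rng.normal(3 + up_shift, 0.3, 6)])
        d = np.concatenate([rng.normal(5, 0.3, 6), rng.normal(5 - up_shift, 0.3, 6)])
        lin = pd.DataFrame({"u": 2.0**u, "d": 2.0**d}, index=idx).T
        return build_ratios(lin, ["u"], ["d"]), groups

    def test_identical_groups_not_significant(self, rng):
        rm, groups = self.build(rng, up_shift=0.0)
        assert not ratio_tests(rm, groups)["significant"].any()

    def test_planted_separation_significant(self, rng):
        rm, groups = self.build(rng, up_shift=1.0)  # 2 log2 units of ratio shift
        assert ratio_tests(rm, groups)["significant"].all()

    def test_row_count_matches_ratio_count(self, rng):
        up = [f"u{i}" for i in range(5)]
        down = [f"d{i}" for i in range(10)]
        idx = [f"b{i}" for i in range(5)] + [f"m{i}" for i in range(5)]
        groups = pd.Series(["B"] * 5 + ["M"] * 5, index=idx)
        lin = pd.DataFrame(
            rng.uniform(0.5, 4, size=(15, 10)), index=up + down, columns=idx
        )
        rm = build_ratios(lin, up, down)
        summary = summarize_ratios(rm, groups)
        assert len(summary) == 50
        assert {"t", "p", "significant", "auc", "threshold", "youden_j"} <= set(summary.columns)
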