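import numpy as np
import pandas as pd
import pytest

from mirsig import ExpressionMatrix, GroupDesign, default_study_params, simulate_study


def make_matrix(values: dict[str, list[float]], n_b: int, n_m: int) -> ExpressionMatrix:
    """Expression matrix from per-miRNA value lists; first n_b samples are B."""
    samples = [f"B{i}" for i in range(1, n_b + 1)] + [f"M{i}" for i in range(1, n_m + 1)]
    groups = pd.Series(["B"] * n_b + ["M"] * n_m, index=samples)
    return ExpressionMatrix(pd.DataFrame(values, index=samples).T, groups)


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 B vs 3 M samples; 'gene-a' separates the groups by 4 log2 units."""
    return make_matrix(
        {
            "gene-a": [4, 5, 6, 8, 9, 10],
            "gene-b": [7, 7, 7, 7, 7, 7],
            "gene-c": [6, 6.5, 6.2, 6.1, 6.4, 6.3],
        },
        3,
        3,
    )


@pytest.fixture(scope="session")
def study():
    """One simulated study at the reference design (11 B vs 12 M)."""
    return simulate_study(GroupDesign(), default_study_params(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20230)
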