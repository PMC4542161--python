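import itertools

import numpy as np
import pandas as pd
import pytest

import nashlipidomics as nl


@pytest.fixture(scope="session")
def cat() -> nl.LipidCatalogue:
    return nl.reference_catalogue()


@pytest.fixture(scope="session")
def panel() -> pd.DataFrame:
    return nl.reference_panel()


@pytest.fixture(scope="session")
def design() -> nl.StudyDesign:
    return nl.StudyDesign()


@pytest.fixture(scope="session")
def sheet_8w() -> pd.DataFrame:
    """Two five-sample cells at 8 weeks."""
    recs = [(f"HFD8w_{i}", "HFD", 8) for i in range(1, 6)]
    recs += [(f"STAM8w_{i}", "STAM", 8) for i in range(1, 6)]
    return pd.DataFrame(recs, columns=["sample", "group", "age_weeks"]).set_index("sample")


def mann_whitney_oracle(a, b) -> tuple[float, float]:
    """Brute-force exact Mann-Whitney: pairwise-count U over every labeling.

    Independent of the implementation under test: U is computed by direct
    pair counting (0.5 per tie) rather than rank sums, and the p-value by
    explicit enumeration with itertools.
    """
    a, b = list(a), list(b)
    pooled = a + b
    m, n = len(a), len(b)

    def u_min(xs, ys):
        ua = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in xs for y in ys)
        return min(ua, m * n - ua)

    observed = u_min(a, b)
    hits = total = 0
    indices = set(range(m + n))
    for subset in itertools.combinations(range(m + n), m):
        xs = [pooled[i] for i in subset]
        ys = [pooled[i] for i in indices - set(subset)]
        total += 1
        if u_min(xs, ys) <= observed + 1e-9:
            hits += 1
    return observed, hits / total


@pytest.fixture(scope="session")
def mw_oracle():
    return mann_whitney_oracle


def toy_norm_table(values: dict[str, list[float]], samples: list[str]) -> pd.DataFrame:
    return pd.DataFrame(values, index=samples).T.rename_axis("name")


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
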