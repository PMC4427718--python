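import numpy as np
import pandas as pd
import pytest

from ajlung.datasets import TABLE1_GROUPS, TABLE2_GROUPS, build_sample_sheet
from ajlung.interaction import build_design_matrix


@pytest.fixture(scope="session")
def table1_sheet() -> pd.DataFrame:
    return build_sample_sheet(TABLE1_GROUPS)


@pytest.fixture(scope="session")
def table2_sheet() -> pd.DataFrame:
    return build_sample_sheet(TABLE2_GROUPS)


@pytest.fixture(scope="session")
def table1_design(table1_sheet) -> pd.DataFrame:
    return build_design_matrix(table1_sheet)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def separable_tumor_dataset(rng):
    """Two tumor classes (8 sham vs 9 high-dose) with 10 genes carrying a
    large mean shift among 200 null genes: linearly separable."""
    n_sham, n_high = 8, 9
    ids = [f"T_sham_{i:02d}" for i in range(n_sham)] + [
        f"T_H_{i:02d}" for i in range(n_high)
    ]
    labels = pd.Series(["sham"] * n_sham + ["H"] * n_high, index=ids)
    genes = [f"g{i:04d}" for i in range(210)]
    m = pd.DataFrame(
        rng.normal(8.0, 0.25, (210, n_sham + n_high)), index=genes, columns=ids
    )
    planted = genes[:10]
    m.loc[planted, labels == "H"] += 3.0
    return m, labels, planted
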