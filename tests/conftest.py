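import numpy as np
import pandas as pd
import pytest

from diceglyph import (
    FixtureConfig,
    VariableRoles,
    make_pbmc_like,
    make_zebra_like,
    validate_table,
)

DICE_ROLES = VariableRoles(row_var="cell_type", col_var="gene", dot_var="condition")


def small_dice_df() -> pd.DataFrame:
    """Three cell types x three genes x four conditions, hand-enumerable."""
    rows = [
        ("T", "g1", "YM"), ("T", "g1", "OM"), ("T", "g2", "YF"),
        ("B", "g1", "YM"), ("B", "g3", "OF"), ("B", "g3", "YF"),
        ("NK", "g2", "YF"), ("NK", "g2", "OF"),
    ]
    return pd.DataFrame(rows, columns=["cell_type", "gene", "condition"])


@pytest.fixture
def small_table():
    return validate_table(small_dice_df(), DICE_ROLES, mode="dice")


def random_dice_table(rng: np.random.Generator, max_records: int = 50):
    """A random validated dice table with <= 6 dot levels."""
    n_rows = int(rng.integers(1, 6))
    n_cols = int(rng.integers(1, 6))
    n_dots = int(rng.integers(1, 7))
    n_rec = int(rng.integers(1, max_records + 1))
    df = pd.DataFrame(
        {
            "cell_type": [f"r{rng.integers(n_rows)}" for _ in range(n_rec)],
            "gene": [f"c{rng.integers(n_cols)}" for _ in range(n_rec)],
            "condition": [f"d{rng.integers(n_dots)}" for _ in range(n_rec)],
        }
    ).drop_duplicates()
    return validate_table(df, DICE_ROLES, mode="dice")


@pytest.fixture(scope="session")
def pbmc_table():
    return make_pbmc_like(FixtureConfig(seed=7))


@pytest.fixture(scope="session")
def zebra_table():
    return make_zebra_like(FixtureConfig(seed=7))
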