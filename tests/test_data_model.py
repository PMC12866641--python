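"""Input validation, level registries, deduplication, presence profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diceglyph import VariableRoles, presence_matrix, validate_table
from diceglyph.errors import (
    EmptyInput,
    MissingColumn,
    NonBinarySplit,
    NonNumericValue,
    TooManyLevels,
)

from conftest import DICE_ROLES, random_dice_table, small_dice_df


def _df(rows, cols=("cell_type", "gene", "condition")):
    return pd.DataFrame(rows, columns=list(cols))


class TestValidateTable:
    def test_four_condition_table_registers_four_levels(self):
        rows = [("T", "g1", c) for c in ("YM", "OM", "YF", "OF")]
        t = validate_table(_df(rows), DICE_ROLES)
        assert t.levels("dot") == ["YM", "OM", "YF", "OF"]

    def test_single_record_is_valid_with_singleton_registries(self):
        t = validate_table(_df([("T", "g1", "YM")]), DICE_ROLES)
        assert all(len(t.levels(r)) == 1 for r in ("row", "col", "dot"))

    def test_six_dot_levels_accepted_seven_rejected(self):
        six = _df([("T", "g1", f"d{i}") for i in range(6)])
        assert len(validate_table(six, DICE_ROLES).dot_levels) == 6
        seven = _df([("T", "g1", f"d{i}") for i in range(7)])
        with pytest.raises(TooManyLevels, match="d6"):
            validate_table(seven, DICE_ROLES)

    def test_missing_role_column(self):
        with pytest.raises(MissingColumn, match="condition"):
            validate_table(_df([("T", "g1")], cols=("cell_type", "gene")), DICE_ROLES)

    def test_empty_input(self):
        with pytest.raises(EmptyInput):
            validate_table(pd.DataFrame(columns=["cell_type", "gene", "condition"]), DICE_ROLES)

    def test_duplicates_collapse_first_wins_and_warn(self):
        rows = [("T", "g1", "YM"), ("T", "g1", "YM"), ("T", "g1", "OM")]
        with pytest.warns(UserWarning, match="1 duplicate"):
            t = validate_table(_df(rows), DICE_ROLES)
        assert len(t.records) == 2
        assert t.n_duplicates_dropped == 1

    def test_validation_is_idempotent(self, small_table):
        again = validate_table(small_table.records, small_table.roles, mode="dice")
        pd.testing.assert_frame_equal(again.records, small_table.records)
        assert again.level_registry == small_table.level_registry

    def test_declared_factor_order_wins_over_appearance(self):
        t = validate_table(
            small_dice_df(), DICE_ROLES, factor_orders={"dot": ["OF", "YF", "OM", "YM"]}
        )
        assert t.levels("dot") == ["OF", "YF", "OM", "YM"]

    def test_missing_value_in_required_role_rejected(self):
        df = _df([("T", "g1", "YM"), ("T", None, "OM")])
        with pytest.raises(Exception, match="missing value"):
            validate_table(df, DICE_ROLES)


class TestDominoValidation:
    ROLES = VariableRoles(
        row_var="ct", col_var="gene", contrast_var="contrast",
        split_var="sex", color_var="lfc", size_var="sig",
    )

    def _domino_df(self, sexes=("F", "M")):
        rows = [
            ("Mic", "APOE", "AD vs CT", s, 1.5 * (1 if s == "F" else -1), 2.0)
            for s in sexes
        ]
        return pd.DataFrame(rows, columns=["ct", "gene", "contrast", "sex", "lfc", "sig"])

    def test_dot_var_aliases_contrast_when_omitted(self):
        t = validate_table(self._domino_df(), self.ROLES, mode="domino")
        assert t.roles.dot_var == "contrast"
        assert t.dot_levels == ["AD vs CT"]

    def test_non_binary_split_rejected(self):
        with pytest.raises(NonBinarySplit, match="1 observed"):
            validate_table(self._domino_df(sexes=("F",)), self.ROLES, mode="domino")

    def test_domino_requires_value_roles(self):
        roles = VariableRoles(row_var="ct", col_var="gene", contrast_var="contrast")
        with pytest.raises(MissingColumn, match="color_var"):
            validate_table(self._domino_df(), roles, mode="domino")

    def test_non_numeric_effect_rejected(self):
        df = self._domino_df().astype({"lfc": object})
        df.loc[0, "lfc"] = "high"
        with pytest.raises(NonNumericValue, match="lfc"):
            validate_table(df, self.ROLES, mode="domino")

    def test_negative_significance_rejected(self):
        df = self._domino_df()
        df.loc[0, "sig"] = -1.0
        with pytest.raises(NonNumericValue, match="nonnegative"):
            validate_table(df, self.ROLES, mode="domino")

    def test_missing_values_stay_nan_not_error(self):
        df = self._domino_df()
        df.loc[0, "lfc"] = np.nan
        t = validate_table(df, self.ROLES, mode="domino")
        assert np.isnan(t.records["lfc"].iloc[0])


class TestPresenceMatrix:
    def test_hand_enumerated_profiles(self):
        rows = [("r1", "c1", "A"), ("r1", "c2", "B"), ("r2", "c1", "A")]
        t = validate_table(_df(rows), DICE_ROLES)
        pm = presence_matrix(t, "row")
        assert pm.labels == ["r1", "r2"]
        assert pm.dot_levels == ["A", "B"]
        assert pm.profile.tolist() == [[1, 1], [1, 0]]

    def test_saturated_table_gives_all_ones(self):
        rows = [(r, c, d) for r in "xy" for c in "uv" for d in "AB"]
        pm = presence_matrix(validate_table(_df(rows), DICE_ROLES), "col")
        assert pm.profile.tolist() == [[1, 1], [1, 1]]

    def test_declared_but_unobserved_label_gets_all_zero_profile(self):
        t = validate_table(
            _df([("r1", "c1", "A")]), DICE_ROLES, factor_orders={"row": ["r0", "r1"]}
        )
        pm = presence_matrix(t, "row")
        assert pm.labels == ["r0", "r1"]
        assert pm.profile.tolist() == [[0], [1]]

    def test_invariant_to_record_order(self):
        df = small_dice_df()
        t1 = validate_table(df, DICE_ROLES)
        t2 = validate_table(df.iloc[::-1].reset_index(drop=True), DICE_ROLES)
        pm1, pm2 = presence_matrix(t1, "row"), presence_matrix(t2, "row")
        # Same profiles per label regardless of registry permutation.
        d1 = dict(zip(pm1.labels, pm1.profile[:, [pm1.dot_levels.index(l) for l in sorted(pm1.dot_levels)]].tolist()))
        d2 = dict(zip(pm2.labels, pm2.profile[:, [pm2.dot_levels.index(l) for l in sorted(pm2.dot_levels)]].tolist()))
        assert d1 == d2

    @pytest.mark.parametrize("seed", range(10))
    def test_profile_sum_matches_groupby_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = random_dice_table(rng)
        for axis, col in (("row", "cell_type"), ("col", "gene")):
            pm = presence_matrix(t, axis)
            oracle = t.records.groupby(col)["condition"].nunique()
            for i, lab in enumerate(pm.labels):
                assert pm.profile[i].sum() == oracle.get(lab, 0)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["r1", "r2", "r3"]),
                st.sampled_from(["c1", "c2"]),
                st.sampled_from(list("ABCDEF")),
            ),
            min_size=1,
            max_size=40,
        )
    )
    def test_presence_bit_iff_record_exists(self, rows):
        t = validate_table(_df(sorted(set(rows))), DICE_ROLES)
        pm = presence_matrix(t, "row")
        observed = {(r, d) for r, _, d in rows}
        for i, lab in enumerate(pm.labels):
            for k, lev in enumerate(pm.dot_levels):
                assert pm.profile[i, k] == int((lab, lev) in observed)
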