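"""Axis ordering: Jaccard distances, deterministic clustering, manual factors."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from diceglyph import (
    PresenceMatrix,
    binary_distance,
    hierarchical_order,
    presence_matrix,
    resolve_axis_order,
    validate_table,
)
from diceglyph.errors import BadManualOrder

from conftest import DICE_ROLES, small_dice_df


def _pm(profiles, labels=None):
    profiles = np.asarray(profiles, dtype=np.int8)
    labels = labels or [f"L{i}" for i in range(profiles.shape[0])]
    dots = [f"d{k}" for k in range(profiles.shape[1])]
    return PresenceMatrix(axis="row", labels=list(labels), dot_levels=dots, profile=profiles)


def brute_jaccard(a, b):
    """Set-based Jaccard distance on binary vectors; 0 for two empty sets."""
    sa = {i for i, x in enumerate(a) if x}
    sb = {i for i, x in enumerate(b) if x}
    if not sa and not sb:
        return 0.0
    return 1.0 - len(sa & sb) / len(sa | sb)


class TestBinaryDistance:
    def test_hand_computed_half_overlap(self):
        d = binary_distance(_pm([[1, 1, 0], [1, 0, 0]]))
        assert d[0, 1] == pytest.approx(0.5)

    def test_identical_profiles_distance_zero(self):
        d = binary_distance(_pm([[1, 0, 1], [1, 0, 1]]))
        assert d[0, 1] == 0.0

    def test_disjoint_profiles_distance_one(self):
        d = binary_distance(_pm([[1, 0], [0, 1]]))
        assert d[0, 1] == 1.0

    def test_two_all_zero_profiles_distance_zero_by_convention(self):
        d = binary_distance(_pm([[0, 0], [0, 0]]))
        assert d[0, 1] == 0.0

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(0, 1), min_size=1, max_size=6),
            min_size=2,
            max_size=6,
        ).filter(lambda ps: len({len(p) for p in ps}) == 1)
    )
    def test_matches_brute_force_oracle_on_short_vectors(self, profiles):
        d = binary_distance(_pm(profiles))
        assert d.shape == (len(profiles), len(profiles))
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        for i, j in itertools.combinations(range(len(profiles)), 2):
            assert d[i, j] == pytest.approx(brute_jaccard(profiles[i], profiles[j]))


class TestHierarchicalOrder:
    def test_single_label_identity(self):
        assert hierarchical_order(np.zeros((1, 1)), ["only"]) == ("only",)

    def test_identical_pair_ends_up_adjacent(self):
        # Two identical profiles, one disjoint: the identical pair must be
        # adjacent in every valid dendrogram leaf order.
        pm = _pm([[1, 0], [0, 1], [1, 0]], labels=["a", "far", "b"])
        order = hierarchical_order(binary_distance(pm), pm.labels)
        assert abs(order.index("a") - order.index("b")) == 1

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("n", [2, 5, 12, 20])
    def test_output_is_permutation(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        d = squareform(np.round(
            np.linalg.norm(pts[:, None] - pts[None], axis=-1)[np.triu_indices(n, 1)], 9
        ))
        labels = [f"L{i:02d}" for i in range(n)]
        order = hierarchical_order(d, labels)
        assert sorted(order) == sorted(labels)

    @pytest.mark.parametrize("seed", range(8))
    def test_merge_blocks_agree_with_scipy_average_linkage(self, seed):
        # With tie-free distances the average-linkage tree is unique, so
        # every merged cluster from scipy's tree must form a contiguous
        # block in our leaf order.
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 10))
        pts = rng.normal(size=(n, 2))
        dm = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        labels = [f"L{i}" for i in range(n)]
        order = hierarchical_order(dm, labels)
        pos = {lab: i for i, lab in enumerate(order)}
        Z = linkage(squareform(dm), method="average")
        members = {i: {i} for i in range(n)}
        for k, (a, b, _, _) in enumerate(Z):
            merged = members[int(a)] | members[int(b)]
            members[n + k] = merged
            positions = sorted(pos[labels[i]] for i in merged)
            assert positions == list(range(positions[0], positions[0] + len(positions)))

    def test_lexicographic_tie_break_is_label_not_index_based(self):
        # Four equidistant labels: every merge ties, so the order must be
        # fully determined by label names, whatever the input order.
        d = np.ones((4, 4)) - np.eye(4)
        for perm in itertools.permutations(["b", "d", "a", "c"]):
            idx = np.argsort([ord(x) for x in perm])  # same matrix, all-ones
            order = hierarchical_order(d, list(perm))
            assert order == ("a", "b", "c", "d")


class TestResolveAxisOrder:
    def test_manual_echoes_list(self, small_table):
        order = resolve_axis_order(small_table, "row", ["NK", "B", "T"])
        assert order.labels == ("NK", "B", "T") and order.method == "manual"

    def test_as_is_returns_registry_order(self, small_table):
        order = resolve_axis_order(small_table, "row", "as-is")
        assert order.labels == ("T", "B", "NK")

    def test_bad_manual_order_lists_missing_and_extra(self, small_table):
        with pytest.raises(BadManualOrder, match=r"missing=\['NK'\].*extra=\['XX'\]"):
            resolve_axis_order(small_table, "row", ["T", "B", "XX"])

    def test_cluster_groups_identical_condition_profiles_adjacently(self):
        # Two cell types share the exact same condition profile; a third is
        # disjoint: clustering must place the twins next to each other.
        rows = (
            [("CD4 T", g, c) for g in ("g1", "g2") for c in ("YF", "OF")]
            + [("CD8 T", g, c) for g in ("g1", "g2") for c in ("YF", "OF")]
            + [("NK", "g3", "YM"), ("NK", "g3", "OM")]
        )
        t = validate_table(pd.DataFrame(rows, columns=["cell_type", "gene", "condition"]), DICE_ROLES)
        order = resolve_axis_order(t, "row", "cluster")
        assert abs(order.labels.index("CD4 T") - order.labels.index("CD8 T")) == 1

    def test_cluster_order_invariant_to_record_order(self):
        df = small_dice_df()
        orders = set()
        for frame in (df, df.iloc[::-1].reset_index(drop=True), df.sample(frac=1, random_state=3)):
            t = validate_table(frame.reset_index(drop=True), DICE_ROLES)
            orders.add(resolve_axis_order(t, "row", "cluster").labels)
            orders.add(resolve_axis_order(t, "col", "cluster").labels and
                       resolve_axis_order(t, "col", "cluster").labels)
        # one row order and one col order across all record permutations
        assert len({o for o in orders if o and o[0] in ("T", "B", "NK")}) == 1
        assert len({o for o in orders if o and o[0].startswith("g")}) == 1
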