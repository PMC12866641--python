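"""Row/column orderings: manual factors or clustering of presence profiles.

Axis labels can be ordered three ways: ``as-is`` (level-registry order),
``manual`` (a user-declared factor), or ``cluster``.  Clustering operates on
the binary presence profiles — which pip positions are filled for each
label, marginal over the other axis — so labels with similar dot patterns
end up adjacent.  The default metric is Jaccard distance (natural for
binary presence data) with average-linkage agglomeration; Hamming and
single/complete linkage are available as options.

The agglomeration is implemented here rather than delegated so that ties in
merge height are broken by lexicographic label comparison, making the leaf
order a pure function of the label -> profile mapping: permuting input
records (and hence the registry) can never change a cluster ordering.
scipy's linkage serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data_model import LongTable, PresenceMatrix, presence_matrix
from .errors import BadManualOrder, DiceGlyphError

_METRICS = ("jaccard", "hamming")
_LINKAGES = ("average", "single", "complete")


@dataclass(frozen=True)
class AxisOrder:
    """A permutation of one axis' level registry plus its provenance."""

    axis: str
    labels: tuple[str, ...]
    method: str


def binary_distance(pm: PresenceMatrix, metric: str = "jaccard") -> np.ndarray:
    """Pairwise distance matrix between binary presence profiles.

    Jaccard distance of two all-zero profiles is 0 by convention (they are
    indistinguishable, hence maximally similar).
    """
    if metric not in _METRICS:
        raise DiceGlyphError(f"unknown metric {metric!r}; expected one of {_METRICS}")
    x = pm.profile.astype(bool)
    n = x.shape[0]
    if n == 1:
        return np.zeros((1, 1))
    # scipy's jaccard already returns 0 for two all-zero vectors.
    d = squareform(pdist(x, metric=metric))
    np.fill_diagonal(d, 0.0)
    return d


def hierarchical_order(
    d: np.ndarray,
    labels: Sequence[str],
    linkage: str = "average",
) -> tuple[str, ...]:
    """Leaf order of a deterministic agglomerative clustering.

    At every step the two closest clusters merge; cluster-to-cluster
    distance is the average (or min/max) of the label-level distances.
    When several pairs tie at the minimal height, the pair whose
    lexicographically smallest member labels sort first merges first, and
    within a merge the cluster holding the smaller minimum label goes left.
    This removes the left/right child ambiguity of a dendrogram without
    depending on input index order.
    """
    if linkage not in _LINKAGES:
        raise DiceGlyphError(f"unknown linkage {linkage!r}; expected one of {_LINKAGES}")
    labels = [str(x) for x in labels]
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise DiceGlyphError(f"distance matrix shape {d.shape} != ({n}, {n})")
    if n <= 1:
        return tuple(labels)

    reducer = {"average": np.mean, "single": np.min, "complete": np.max}[linkage]
    # Active clusters: leaf order, member indices, lexicographic min label.
    clusters: list[dict] = [
        {"leaves": [lab], "idx": [i], "min": lab} for i, lab in enumerate(labels)
    ]

    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca, cb = clusters[a], clusters[b]
                height = float(reducer(d[np.ix_(ca["idx"], cb["idx"])]))
                key = (height, *sorted((ca["min"], cb["min"])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        ca, cb = clusters[a], clusters[b]
        left, right = (ca, cb) if ca["min"] <= cb["min"] else (cb, ca)
        merged = {
            "leaves": left["leaves"] + right["leaves"],
            "idx": ca["idx"] + cb["idx"],
            "min": min(ca["min"], cb["min"]),
        }
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)

    return tuple(clusters[0]["leaves"])


def cluster_order(
    table: LongTable,
    axis: str,
    metric: str = "jaccard",
    linkage: str = "average",
) -> AxisOrder:
    """Cluster one axis by its presence profiles and return the leaf order."""
    pm = presence_matrix(table, axis)
    d = binary_distance(pm, metric=metric)
    return AxisOrder(axis=axis, labels=hierarchical_order(d, pm.labels, linkage), method="cluster")


def resolve_axis_order(
    table: LongTable,
    axis: str,
    spec: str | Sequence[str] = "as-is",
    metric: str = "jaccard",
    linkage: str = "average",
) -> AxisOrder:
    """Resolve an ordering request for one axis.

    ``spec`` is ``"as-is"`` (registry order), ``"cluster"``, or an explicit
    label list (manual order, which must be a permutation of the observed
    registry).
    """
    registry = table.levels(axis)
    if isinstance(spec, str):
        if spec == "as-is":
            return AxisOrder(axis=axis, labels=tuple(registry), method="as-is")
        if spec == "cluster":
            return cluster_order(table, axis, metric=metric, linkage=linkage)
        raise DiceGlyphError(
            f"unknown axis order spec {spec!r}; expected 'as-is', 'cluster' "
            "or an explicit label list"
        )
    manual = [str(x) for x in spec]
    missing = sorted(set(registry) - set(manual))
    extra = sorted(set(manual) - set(registry))
    if missing or extra or len(manual) != len(registry):
        raise BadManualOrder(
            f"manual {axis} order is not a permutation of the observed "
            f"labels; missing={missing}, extra={extra}"
        )
    return AxisOrder(axis=axis, labels=tuple(manual), method="manual")
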