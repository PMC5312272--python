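"""Enrichment-score machinery and the bidirectional transcriptional distance.

The similarity between two ranked lists is scored with the classic
(unweighted) Kolmogorov-Smirnov enrichment statistic on the extreme sets of
each list, combined into a total enrichment score (TES) and averaged in both
directions.  The resulting distance lives on [0, 2]: 0 for identical
rankings, 2 for exactly opposed ones, ~1 for unrelated ones.

The unweighted KS statistic is the only well-defined choice here: drug PRLs
carry ranks only, never expression magnitudes, so the score-weighted GSEA
variant has no input to weight by.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sigrev.ranking import GeneSetPair, RankedList, extremes


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise transcriptional distances between named nodes."""

    node_ids: tuple[str, ...]
    values: np.ndarray
    s: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        k = len(self.node_ids)
        if vals.shape != (k, k):
            raise ValueError(f"matrix shape {vals.shape} != ({k}, {k})")
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(vals) != 0.0):
            raise ValueError("distance matrix diagonal must be exactly 0")
        if vals.min() < -1e-12 or vals.max() > 2 + 1e-12:
            raise ValueError("distances must lie in [0, 2]")
        object.__setattr__(self, "node_ids", tuple(self.node_ids))
        object.__setattr__(self, "values", vals)

    def get(self, a: str, b: str) -> float:
        i = self.node_ids.index(a)
        j = self.node_ids.index(b)
        return float(self.values[i, j])


def enrichment_score(S: set[str] | frozenset[str], r: RankedList) -> float:
    """Signed KS enrichment score of gene set ``S`` in ranking ``r``.

    Walk the ranking from position 1 to N keeping a running sum: add
    ``1/|S|`` on a hit (feature in ``S``) and subtract ``1/(N-|S|)`` on a
    miss.  The score is the deviation of maximum absolute value, sign
    retained; on an exact tie in magnitude between the positive and negative
    extremes the positive one is returned.  +1 means ``S`` occupies the very
    top of the ranking, -1 the very bottom.
    """
    S = frozenset(S)
    n = r.n
    k = len(S)
    if k == 0:
        raise ValueError("gene set is empty")
    if k >= n:
        raise ValueError(f"gene set must be a strict subset of the ranking (|S|={k}, N={n})")
    extra = S - r.universe
    if extra:
        raise ValueError(f"gene set members absent from ranking: {sorted(extra)[:10]}")

    # hit positions, ascending; the running sum is piecewise linear between
    # hits, so its extrema occur immediately after a hit (candidates for the
    # maximum) or immediately before one (candidates for the minimum).
    # Scaling by k*(n-k) makes every value an integer, so the extreme and the
    # declared tie rule (positive beats negative of equal magnitude) are
    # evaluated exactly; only the final result is floating point.
    pos = np.sort(np.asarray(r.positions(S), dtype=np.int64))
    i = np.arange(1, k + 1, dtype=np.int64)
    after = i * (n - k) - (pos - i) * k           # value just after hit i
    before = after - (n - k)                      # value just before hit i
    max_dev = max(int(after.max()), 0)
    min_dev = min(int(before.min()), 0)
    best = max_dev if max_dev >= -min_dev else min_dev
    return best / (k * (n - k))


def tes(q: GeneSetPair, r: RankedList) -> float:
    """Total enrichment score of a query extreme-set pair against a ranking.

    ``tes = 1 - (ES(up, r) - ES(down, r)) / 2``: 0 when the query's up genes
    sit at the top of ``r`` and its down genes at the bottom (identical
    regulation), 2 in the exactly opposed case, ~1 when unrelated.
    """
    es_up = enrichment_score(q.up, r)
    es_down = enrichment_score(q.down, r)
    return 1.0 - (es_up - es_down) / 2.0


def distance(x: RankedList, y: RankedList, s: int) -> float:
    """Bidirectional transcriptional distance between two ranked lists.

    The average of the two directional TES values: the extremes of ``x``
    scored against ``y`` and vice versa.  Symmetric by construction, 0 for
    identical profiles, 2 for a ranking and its reverse.
    """
    if x.universe != y.universe:
        diff = sorted(x.universe ^ y.universe)
        raise ValueError(
            f"feature universes of {x.node_id!r} and {y.node_id!r} differ; "
            f"symmetric difference: {diff[:10]}"
        )
    return (tes(extremes(x, s), y) + tes(extremes(y, s), x)) / 2.0


def distance_matrix(nodes: list[RankedList], s: int) -> DistanceMatrix:
    """All pairwise distances between the given nodes (shared universe)."""
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes")
    ids = [nd.node_id for nd in nodes]
    if len(set(ids)) != len(ids):
        raise ValueError("node ids must be unique")
    k = len(nodes)
    vals = np.zeros((k, k), dtype=float)
    ext = [extremes(nd, s) for nd in nodes]
    universe = nodes[0].universe
    for nd in nodes[1:]:
        if nd.universe != universe:
            diff = sorted(universe ^ nd.universe)
            raise ValueError(
                f"feature universe of {nd.node_id!r} differs from "
                f"{nodes[0].node_id!r}; symmetric difference: {diff[:10]}"
            )
    for i in range(k):
        for j in range(i + 1, k):
            d = (tes(ext[i], nodes[j]) + tes(ext[j], nodes[i])) / 2.0
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(node_ids=tuple(ids), values=vals, s=s)
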