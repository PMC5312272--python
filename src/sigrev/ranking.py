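"""Ranked gene signatures: construction, reversal, extremes, and aggregation.

A :class:`RankedList` is the universal currency of the pipeline: a total order
over unique feature ids (probe sets or gene symbols), position 1 being the
most up-regulated feature and position N the most down-regulated one.  Drug
prototype ranked lists (PRLs) and disease query signatures are both held in
this type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


@dataclass(frozen=True)
class RankedList:
    """A total order over unique feature ids.

    Parameters
    ----------
    node_id:
        Label of the node this ranking belongs to (a drug name or a query
        signature name).
    features:
        Feature ids ordered from most up-regulated (position 1) to most
        down-regulated (position N).
    scores:
        Optional mapping feature id -> signed differential-expression value
        that produced the order.  When present the order must be
        non-increasing in score, ties broken lexicographically by feature id.
    """

    node_id: str
    features: tuple[str, ...]
    scores: dict[str, float] | None = None

    # position lookup built lazily; object.__setattr__ because frozen
    _pos: dict[str, int] = field(
        default=None, repr=False, compare=False, hash=False  # type: ignore[arg-type]
    )

    def __post_init__(self) -> None:
        feats = tuple(str(f) for f in self.features)
        object.__setattr__(self, "features", feats)
        if len(feats) < 1:
            raise ValueError(f"ranked list {self.node_id!r} is empty")
        pos = {f: i + 1 for i, f in enumerate(feats)}
        if len(pos) != len(feats):
            seen: set[str] = set()
            dups = sorted({f for f in feats if f in seen or seen.add(f)})
            raise ValueError(f"duplicate feature ids in {self.node_id!r}: {dups}")
        object.__setattr__(self, "_pos", pos)
        if self.scores is not None:
            sc = {str(k): float(v) for k, v in self.scores.items()}
            if set(sc) != set(feats):
                raise ValueError(
                    f"scores of {self.node_id!r} do not cover the feature set"
                )
            # only non-increasing is required: reversal flips the relative
            # order of tied features, so a lexicographic tie constraint here
            # would outlaw reverse_signature on lists with tied scores
            for a, b in zip(feats, feats[1:]):
                if sc[a] < sc[b]:
                    raise ValueError(
                        f"order of {self.node_id!r} inconsistent with scores "
                        f"at {a!r}/{b!r}"
                    )
            object.__setattr__(self, "scores", sc)

    def __len__(self) -> int:
        return len(self.features)

    @property
    def n(self) -> int:
        return len(self.features)

    def position(self, feature: str) -> int:
        """1-based position of ``feature`` in the ranking."""
        return self._pos[feature]

    def positions(self, features: Iterable[str]) -> list[int]:
        pos = self._pos
        return [pos[f] for f in features]

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self._pos)

    def with_node_id(self, node_id: str) -> "RankedList":
        return RankedList(node_id=node_id, features=self.features, scores=self.scores)


@dataclass(frozen=True)
class GeneSetPair:
    """Top-s ("up") and bottom-s ("down") extreme sets of a ranking."""

    up: frozenset[str]
    down: frozenset[str]
    s: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        if len(self.up) != self.s or len(self.down) != self.s:
            raise ValueError(
                f"extreme sets must both have size s={self.s}; "
                f"got |up|={len(self.up)}, |down|={len(self.down)}"
            )
        if self.up & self.down:
            raise ValueError("up and down sets overlap")


def rank_from_scores(
    scores: Mapping[str, float], node_id: str = "signature"
) -> RankedList:
    """Rank features by signed differential-expression score, descending.

    Ties are broken lexicographically by feature id so the result is
    deterministic and independent of the mapping's iteration order.

    Raises
    ------
    ValueError
        If fewer than 4 features are given, a value is non-finite, or a
        feature id appears twice (after string normalisation).
    """
    items = [(str(k), float(v)) for k, v in scores.items()]
    if len({k for k, _ in items}) != len(items):
        raise ValueError(f"duplicate feature ids in scores for {node_id!r}")
    if len(items) < 4:
        raise ValueError(f"need >= 4 features to rank, got {len(items)}")
    for k, v in items:
        if not math.isfinite(v):
            raise ValueError(f"non-finite score for feature {k!r}: {v}")
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    return RankedList(
        node_id=node_id,
        features=tuple(k for k, _ in items),
        scores=dict(items),
    )


def reverse_signature(r: RankedList) -> RankedList:
    """Reverse a ranking so position i maps to position N-i+1.

    This is the signature-reversion step: the most down-regulated feature of
    the input becomes the most up-regulated of the output, modelling the
    transcriptional consequence of *inhibiting* the pathway that produced the
    original signature.  Scores, when present, are negated so that the
    order/score invariant is preserved.  The operation is an involution.
    """
    scores = None
    if r.scores is not None:
        scores = {k: -v for k, v in r.scores.items()}
    return RankedList(
        node_id=f"{r.node_id}-reverse",
        features=tuple(reversed(r.features)),
        scores=scores,
    )


def extremes(r: RankedList, s: int) -> GeneSetPair:
    """Extract the top-s and bottom-s feature sets of a ranking."""
    if s < 1:
        raise ValueError(f"s must be >= 1, got {s}")
    if 2 * s > r.n:
        raise ValueError(f"2*s must not exceed N: s={s}, N={r.n}")
    return GeneSetPair(
        up=frozenset(r.features[:s]),
        down=frozenset(r.features[r.n - s:]),
        s=s,
    )


def merge_prl(rs: Sequence[RankedList], node_id: str = "prl") -> RankedList:
    """Aggregate several rankings into one prototype ranked list (Borda).

    Each feature's aggregate score is the sum over input lists of
    ``N - position``; the output ranks features by aggregate score descending,
    ties broken lexicographically.  Merging one list, or k copies of the same
    list, returns that order unchanged.  The result is invariant under
    permutation of the inputs.

    Raises
    ------
    ValueError
        If no lists are given or their feature universes differ (the
        symmetric difference is reported).
    """
    if len(rs) < 1:
        raise ValueError("merge_prl needs at least one ranked list")
    universe = rs[0].universe
    for other in rs[1:]:
        if other.universe != universe:
            diff = sorted(universe ^ other.universe)
            raise ValueError(
                f"feature universes differ between {rs[0].node_id!r} and "
                f"{other.node_id!r}; symmetric difference: {diff}"
            )
    n = rs[0].n
    agg: dict[str, int] = {f: 0 for f in universe}
    for r in rs:
        for i, f in enumerate(r.features):
            agg[f] += n - (i + 1)
    order = sorted(agg, key=lambda f: (-agg[f], f))
    return RankedList(node_id=node_id, features=tuple(order))
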