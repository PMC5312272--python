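"""Querying the drug network: neighbors, intersection, community enrichment,
and candidate target-gene shortlists.

A query node (typically a reversed disease signature) is placed in the drug
network; all drugs within the transcriptional-distance threshold tau become
its neighbors.  Neighbor sets from several query nodes are intersected, and
mode-of-action drug communities are ranked by upper-tail hypergeometric
enrichment of the neighbor set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Sequence

from sigrev.distance import DistanceMatrix
from sigrev.ranking import RankedList

DEFAULT_TAU = 0.86
DEFAULT_ALPHA = 0.05


@dataclass
class DrugNetwork:
    """Named ranked-list nodes with pairwise distances and community labels.

    ``communities`` maps *drug* node ids to community labels; query nodes are
    present in ``nodes``/``dmatrix`` but carry no label and are never
    returned as neighbors nor counted in enrichment universes.  ``tau`` is
    the neighbor-selection distance threshold (inclusive).
    """

    nodes: dict[str, RankedList]
    dmatrix: DistanceMatrix
    communities: dict[str, str] = field(default_factory=dict)
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        if not (0.0 < self.tau <= 2.0):
            raise ValueError(f"tau must lie in (0, 2], got {self.tau}")
        known = set(self.dmatrix.node_ids)
        if set(self.nodes) != known:
            raise ValueError("nodes and distance matrix disagree on node ids")
        stray = sorted(set(self.communities) - known)
        if stray:
            raise ValueError(f"community labels for unknown nodes: {stray[:10]}")

    @property
    def drug_ids(self) -> frozenset[str]:
        """Ids of community-labeled (drug) nodes."""
        return frozenset(self.communities)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of one drug community in a neighbor set."""

    community: str
    k: int      # neighbors inside the community
    K: int      # community size
    n: int      # neighbor-set size
    N_u: int    # universe size (all community-labeled drugs)
    p: float    # upper-tail P(X >= k)
    p_adjusted: float = float("nan")  # Benjamini-Hochberg across communities
    significant: bool = False         # raw p < alpha

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(
                f"inconsistent counts: k={self.k}, K={self.K}, n={self.n}"
            )
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p-value out of range: {self.p}")


def neighbors(query_id: str, net: DrugNetwork) -> frozenset[str]:
    """All drug nodes within distance tau (inclusive) of the query node.

    Only community-labeled nodes qualify — a second query node can never be a
    neighbor, however close it sits.
    """
    if query_id not in net.nodes:
        raise KeyError(f"unknown node id: {query_id!r}")
    out = {
        drug
        for drug in net.drug_ids
        if drug != query_id and net.dmatrix.get(query_id, drug) <= net.tau
    }
    if query_id in net.drug_ids:
        out.add(query_id)  # a drug is at distance 0 from itself
    return frozenset(out)


def intersect_neighbor_sets(sets: Sequence[Iterable[str]]) -> tuple[str, ...]:
    """Drugs common to every neighbor set, in lexicographic order."""
    if len(sets) < 2:
        raise ValueError("need at least 2 neighbor sets to intersect")
    acc = set(sets[0])
    for s in sets[1:]:
        acc &= set(s)
    return tuple(sorted(acc))


def hypergeom_upper(k: int, K: int, n: int, N_u: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts successes in ``n`` draws without replacement from a population
    of ``N_u`` containing ``K`` successes.  Evaluated exactly by summing
    binomial terms in integer arithmetic before a single final division.
    """
    if not (0 <= k <= min(K, n)) or K > N_u or n > N_u or K < 0 or n < 0:
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N_u={N_u}"
        )
    total = comb(N_u, n)
    upper = sum(comb(K, j) * comb(N_u - K, n - j) for j in range(k, min(K, n) + 1))
    return upper / total


def _bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, pvals[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


def community_enrichment(
    neigh: Iterable[str], net: DrugNetwork, alpha: float = DEFAULT_ALPHA
) -> list[EnrichmentResult]:
    """Rank every drug community by hypergeometric enrichment of a neighbor set.

    The universe is the set of community-labeled drugs; neighbor ids outside
    it (query nodes can never appear, but a caller-supplied stray id could)
    are ignored.  Results are sorted by p ascending, then label.  The
    ``significant`` flag uses the raw p-value against ``alpha``;
    Benjamini-Hochberg adjusted p-values are reported alongside but do not
    drive the flag.
    """
    if not net.communities:
        raise ValueError("network has no community labels")
    return community_enrichment_from_labels(neigh, net.communities, alpha=alpha)


def community_enrichment_from_labels(
    neigh: Iterable[str], communities: dict[str, str], alpha: float = DEFAULT_ALPHA
) -> list[EnrichmentResult]:
    """Community enrichment from a drug -> community label map alone.

    The network geometry is not needed once the neighbor set is fixed; this
    is the work-horse behind :func:`community_enrichment` and the ``enrich``
    CLI command.
    """
    if not communities:
        raise ValueError("no community labels given")
    universe = frozenset(communities)
    neigh_set = frozenset(neigh) & universe
    n = len(neigh_set)
    n_u = len(universe)
    members: dict[str, set[str]] = {}
    for drug, community in communities.items():
        members.setdefault(community, set()).add(drug)
    labels = sorted(members)
    pvals = []
    counts = []
    for label in labels:
        k = len(neigh_set & members[label])
        big_k = len(members[label])
        counts.append((k, big_k))
        pvals.append(hypergeom_upper(k, big_k, n, n_u))
    adj = _bh_adjust(pvals)
    results = [
        EnrichmentResult(
            community=label,
            k=k,
            K=big_k,
            n=n,
            N_u=n_u,
            p=p,
            p_adjusted=pa,
            significant=p < alpha,
        )
        for label, (k, big_k), p, pa in zip(labels, counts, pvals, adj)
    ]
    results.sort(key=lambda r: (r.p, r.community))
    return results


def candidate_target_genes(
    rev_sig: RankedList, drug_prl: RankedList, k_extreme: int = 100
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Shortlist genes predicted to be regulated by a drug.

    ``predicted_up`` is the intersection of the top ``k_extreme`` features of
    the reverse signature with the top ``k_extreme`` of the drug PRL;
    ``predicted_down`` the intersection of the two bottom sets.  Both lists
    are ordered by position in the reverse signature.
    """
    if rev_sig.universe != drug_prl.universe:
        diff = sorted(rev_sig.universe ^ drug_prl.universe)
        raise ValueError(
            f"feature universes of {rev_sig.node_id!r} and "
            f"{drug_prl.node_id!r} differ; symmetric difference: {diff[:10]}"
        )
    if 2 * k_extreme > rev_sig.n:
        raise ValueError(f"2*k_extreme must not exceed N: k={k_extreme}, N={rev_sig.n}")
    sig_top = rev_sig.features[:k_extreme]
    sig_bot = rev_sig.features[rev_sig.n - k_extreme:]
    drug_top = frozenset(drug_prl.features[:k_extreme])
    drug_bot = frozenset(drug_prl.features[drug_prl.n - k_extreme:])
    predicted_up = tuple(g for g in sig_top if g in drug_top)
    predicted_down = tuple(g for g in sig_bot if g in drug_bot)
    return predicted_up, predicted_down
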