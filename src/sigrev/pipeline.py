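"""End-to-end repositioning workflow over a drug PRL compendium.

Binds the stages together the way the original study ran them: take one or
more query score tables, rank and reverse them, place the reversed
signatures in the drug network, select neighbors under the distance
threshold, intersect the neighbor sets across query nodes, rank drug
communities by hypergeometric enrichment, and shortlist candidate target
genes for the intersected drugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sigrev.distance import DistanceMatrix, distance
from sigrev.ranking import RankedList
from sigrev.repositioning import (
    DrugNetwork,
    EnrichmentResult,
    candidate_target_genes,
    community_enrichment,
    intersect_neighbor_sets,
    neighbors,
)


def build_network(
    prls: dict[str, RankedList],
    communities: dict[str, str],
    queries: dict[str, RankedList] | None = None,
    s: int = 250,
    tau: float = 0.86,
) -> DrugNetwork:
    """Assemble a drug network from PRLs, community labels and query nodes.

    All pairwise distances are computed; drugs are sorted by id so the
    result is independent of input file listing order.
    """
    queries = queries or {}
    overlap = set(prls) & set(queries)
    if overlap:
        raise ValueError(f"query ids collide with drug ids: {sorted(overlap)[:10]}")
    unlabeled = sorted(set(prls) - set(communities))
    if unlabeled:
        raise ValueError(f"drugs without community label: {unlabeled[:10]}")
    nodes = {name: prls[name] for name in sorted(prls)}
    nodes.update({name: queries[name] for name in sorted(queries)})
    ids = list(nodes)
    k = len(ids)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            vals[i, j] = vals[j, i] = distance(nodes[ids[i]], nodes[ids[j]], s)
    dm = DistanceMatrix(node_ids=tuple(ids), values=vals, s=s)
    labels = {d: communities[d] for d in prls}
    return DrugNetwork(nodes=nodes, dmatrix=dm, communities=labels, tau=tau)


@dataclass
class WorkflowResult:
    """Everything the query workflow produces, ready for serialization."""

    network: DrugNetwork
    query_ids: tuple[str, ...]
    neighbor_sets: dict[str, frozenset[str]]
    intersection: tuple[str, ...]
    enrichment_per_query: dict[str, list[EnrichmentResult]]
    enrichment_intersection: list[EnrichmentResult]
    candidates: dict[tuple[str, str], tuple[tuple[str, ...], tuple[str, ...]]] = field(
        default_factory=dict
    )

    def query_table(self) -> pd.DataFrame:
        """Per-drug distances to every query node plus in-intersection flag."""
        drugs = sorted(self.network.drug_ids)
        data: dict[str, object] = {"drug": drugs}
        data["community"] = [self.network.communities[d] for d in drugs]
        for q in self.query_ids:
            data[f"dist_{q}"] = [self.network.dmatrix.get(q, d) for d in drugs]
        for q in self.query_ids:
            data[f"neighbor_{q}"] = [d in self.neighbor_sets[q] for d in drugs]
        data["in_intersection"] = [d in set(self.intersection) for d in drugs]
        return pd.DataFrame(data)

    def enrichment_table(self, which: str = "intersection") -> pd.DataFrame:
        if which == "intersection":
            results = self.enrichment_intersection
        else:
            results = self.enrichment_per_query[which]
        return pd.DataFrame(
            {
                "community": [r.community for r in results],
                "k": [r.k for r in results],
                "K": [r.K for r in results],
                "n": [r.n for r in results],
                "N_u": [r.N_u for r in results],
                "p": [r.p for r in results],
                "p_adjusted": [r.p_adjusted for r in results],
                "significant": [r.significant for r in results],
            }
        )

    def candidate_table(self) -> pd.DataFrame:
        rows = []
        for (query, drug), (up, down) in sorted(self.candidates.items()):
            for gene in up:
                rows.append((query, drug, "up", gene))
            for gene in down:
                rows.append((query, drug, "down", gene))
        return pd.DataFrame(rows, columns=["query", "drug", "direction", "gene"])


def run_query_workflow(
    net: DrugNetwork,
    query_ids: list[str],
    alpha: float = 0.05,
    k_extreme: int = 100,
    with_candidates: bool = True,
) -> WorkflowResult:
    """Query the network with the given nodes and aggregate the results.

    Neighbor sets are computed per query node; when two or more queries are
    given their intersection is taken, otherwise the single neighbor set
    stands in for it.  Community enrichment is reported both per query node
    and for the intersection.  Candidate target genes are computed for every
    intersected drug against every query signature.
    """
    neighbor_sets = {q: neighbors(q, net) for q in query_ids}
    if len(query_ids) >= 2:
        intersection = intersect_neighbor_sets([neighbor_sets[q] for q in query_ids])
    else:
        intersection = tuple(sorted(neighbor_sets[query_ids[0]]))
    enrichment_per_query = {
        q: community_enrichment(neighbor_sets[q], net, alpha=alpha) for q in query_ids
    }
    enrichment_intersection = community_enrichment(intersection, net, alpha=alpha)
    candidates: dict[tuple[str, str], tuple[tuple[str, ...], tuple[str, ...]]] = {}
    if with_candidates:
        for q in query_ids:
            for drug in intersection:
                candidates[(q, drug)] = candidate_target_genes(
                    net.nodes[q], net.nodes[drug], k_extreme=k_extreme
                )
    return WorkflowResult(
        network=net,
        query_ids=tuple(query_ids),
        neighbor_sets=neighbor_sets,
        intersection=intersection,
        enrichment_per_query=enrichment_per_query,
        enrichment_intersection=enrichment_intersection,
        candidates=candidates,
    )
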