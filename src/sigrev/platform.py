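"""Cross-platform conversion of probe-level rankings via gene symbols.

Microarray platforms index transcripts by probe-set ids, and two platforms
(e.g. Affymetrix Human Gene 1.0 ST and HG-U133A) share genes but not probes.
A ranking produced on one platform is mapped onto another in two steps:

1. *Collapse* the source probe ranking to a gene ranking: every gene takes
   the rank of its best (first-appearing) probe.
2. *Expand* the gene ranking onto the target platform: every target probe
   inherits its gene's position; target probes whose gene is absent from the
   gene ranking are placed at the center of the ranking.

Ties (probes sharing a gene, probes sharing the center) are linearised
lexicographically by probe id, because downstream enrichment-score distances
need a total order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from sigrev.ranking import RankedList


@dataclass(frozen=True)
class AnnotationMap:
    """Probe id -> gene symbol annotation for one array platform.

    ``entries`` maps each annotated probe to exactly one gene (many probes may
    share a gene; a probe annotated to several genes must be de-duplicated
    upstream and is rejected by the TSV loader).  ``probe_universe`` is the
    full probe complement of the platform and may exceed the annotated set.
    """

    platform_id: str
    entries: dict[str, str]
    probe_universe: frozenset[str] = field(default=None)  # type: ignore[arg-type]

    def __post_init__(self) -> None:
        entries = {str(p): str(g) for p, g in self.entries.items()}
        if not entries:
            raise ValueError(f"annotation map {self.platform_id!r} has no entries")
        object.__setattr__(self, "entries", entries)
        if self.probe_universe is None:
            universe = frozenset(entries)
        else:
            universe = frozenset(str(p) for p in self.probe_universe)
            missing = sorted(set(entries) - universe)
            if missing:
                raise ValueError(
                    f"annotated probes missing from probe_universe of "
                    f"{self.platform_id!r}: {missing[:10]}"
                )
        object.__setattr__(self, "probe_universe", universe)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.entries.values())


def collapse_to_genes(r: RankedList, annot: AnnotationMap) -> RankedList:
    """Collapse a probe-level ranking to gene level (best-rank rule).

    Each gene receives the smallest (best) position among its probes — "the
    rank of the probe that comes first in the ranking".  Genes are ordered by
    that position ascending, ties broken lexicographically; probes with no
    annotation are dropped.
    """
    best: dict[str, int] = {}
    for i, probe in enumerate(r.features):
        gene = annot.entries.get(probe)
        if gene is None:
            continue
        if gene not in best:
            best[gene] = i + 1
    if not best:
        raise ValueError(
            f"no probe of {r.node_id!r} is annotated on platform "
            f"{annot.platform_id!r}"
        )
    order = sorted(best, key=lambda g: (best[g], g))
    return RankedList(node_id=r.node_id, features=tuple(order))


def expand_to_platform(g: RankedList, annot: AnnotationMap) -> RankedList:
    """Expand a gene-level ranking onto a target platform's probes.

    Every target probe whose gene appears in ``g`` gets that gene's position
    as a provisional score ("the same ranking to all of the probes
    involved"); probes whose gene is absent, or which are unannotated,
    receive the center score (M+1)/2 where M is the number of ranked genes.
    The output totally orders the full target probe universe by provisional
    score ascending, ties lexicographic by probe id.
    """
    gene_pos = {gene: i + 1 for i, gene in enumerate(g.features)}
    m = len(g.features)
    center = (m + 1) / 2.0
    provisional: dict[str, float] = {}
    matched = 0
    for probe in annot.probe_universe:
        gene = annot.entries.get(probe)
        if gene is not None and gene in gene_pos:
            provisional[probe] = float(gene_pos[gene])
            matched += 1
        else:
            provisional[probe] = center
    if matched == 0:
        raise ValueError(
            f"no probe on platform {annot.platform_id!r} matches any gene of "
            f"{g.node_id!r}"
        )
    order = sorted(provisional, key=lambda p: (provisional[p], p))
    return RankedList(node_id=g.node_id, features=tuple(order))


def convert_platform(
    r: RankedList, src_annot: AnnotationMap, dst_annot: AnnotationMap
) -> RankedList:
    """Convert a probe ranking from one platform to another in two steps."""
    return expand_to_platform(collapse_to_genes(r, src_annot), dst_annot)
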