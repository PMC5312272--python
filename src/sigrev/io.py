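"""Readers and writers for the pipeline's plain-text formats.

All formats are tab- or comma-separated text chosen for diff-ability:

* RNK — two columns (feature id, signed score), no header; the standard
  pre-ranked signature exchange format.
* ranked list — one feature id per line; position = line number (1-based).
* annotation TSV — two columns (probe id, gene symbol) with an optional
  third platform column; ``#`` comment lines skipped.
* probe universe — one probe id per line.
* GMT — one community per line: label, description, member drug ids.
* distance matrix — CSV with node ids as header row and first column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from sigrev.distance import DistanceMatrix
from sigrev.platform import AnnotationMap
from sigrev.ranking import RankedList, rank_from_scores


def read_rnk(path: str | Path, node_id: str | None = None) -> RankedList:
    """Read a two-column RNK file (feature id, signed score) into a ranking."""
    path = Path(path)
    scores: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
        feature, raw = parts
        if feature in scores:
            raise ValueError(f"{path}:{lineno}: duplicate feature id {feature!r}")
        try:
            scores[feature] = float(raw)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad score {raw!r}") from exc
    return rank_from_scores(scores, node_id=node_id or path.stem)


def write_rnk(r: RankedList, path: str | Path) -> None:
    if r.scores is None:
        raise ValueError(f"ranked list {r.node_id!r} has no scores; use write_ranked_list")
    lines = [f"{f}\t{r.scores[f]:.17g}" for f in r.features]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ranked_list(path: str | Path, node_id: str | None = None) -> RankedList:
    """Read a ranked list stored one feature per line (line 1 = rank 1)."""
    path = Path(path)
    feats = [
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return RankedList(node_id=node_id or path.stem, features=tuple(feats))


def write_ranked_list(r: RankedList, path: str | Path) -> None:
    Path(path).write_text("\n".join(r.features) + "\n")


def read_annotation(
    path: str | Path,
    platform_id: str | None = None,
    universe_path: str | Path | None = None,
) -> AnnotationMap:
    """Read a probe->gene annotation TSV.

    A probe annotated to more than one distinct gene is ambiguous and
    rejected, naming the offending probes — the map must be many-probes-to-
    one-gene.  ``universe_path`` optionally supplies the full probe
    complement (one id per line) when it exceeds the annotated probes.
    """
    path = Path(path)
    entries: dict[str, str] = {}
    ambiguous: set[str] = set()
    file_platform: str | None = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) not in (2, 3):
            raise ValueError(f"{path}:{lineno}: expected 2 or 3 tab-separated fields")
        probe, gene = parts[0], parts[1]
        if len(parts) == 3:
            file_platform = parts[2]
        if probe in entries and entries[probe] != gene:
            ambiguous.add(probe)
        entries[probe] = gene
    if ambiguous:
        raise ValueError(
            f"{path}: probes annotated to multiple genes (pre-deduplicate them): "
            f"{sorted(ambiguous)[:10]}"
        )
    universe = None
    if universe_path is not None:
        universe = frozenset(
            line.strip()
            for line in Path(universe_path).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        )
    return AnnotationMap(
        platform_id=platform_id or file_platform or path.stem,
        entries=entries,
        probe_universe=universe,
    )


def write_annotation(annot: AnnotationMap, path: str | Path) -> None:
    lines = [
        f"{p}\t{g}\t{annot.platform_id}" for p, g in sorted(annot.entries.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> dict[str, str]:
    """Read GMT community sets into a member -> community-label mapping."""
    path = Path(path)
    labels: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs label, description and >= 1 member"
            )
        label, members = parts[0], parts[2:]
        for m in members:
            if m in labels:
                raise ValueError(
                    f"{path}:{lineno}: drug {m!r} appears in two communities"
                )
            labels[m] = label
    return labels


def write_gmt(labels: dict[str, str], path: str | Path) -> None:
    by_community: dict[str, list[str]] = {}
    for member, community in labels.items():
        by_community.setdefault(community, []).append(member)
    lines = [
        "\t".join([community, "na", *sorted(members)])
        for community, members in sorted(by_community.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_distance_matrix(path: str | Path, s: int) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: header row and index column disagree")
    return DistanceMatrix(
        node_ids=tuple(str(c) for c in df.columns),
        values=df.to_numpy(dtype=float),
        s=s,
    )


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.values, index=dm.node_ids, columns=dm.node_ids).to_csv(path)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as headered TSV with stable float formatting."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_score_table(path: str | Path) -> dict[str, float]:
    """Read a differential-expression score table (feature id, value TSV).

    Accepts an optional header line whose second field is non-numeric.
    """
    path = Path(path)
    scores: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
        feature, raw = parts
        try:
            value = float(raw)
        except ValueError:
            if lineno == 1:
                continue  # header
            raise ValueError(f"{path}:{lineno}: bad score {raw!r}") from None
        if feature in scores:
            raise ValueError(f"{path}:{lineno}: duplicate feature id {feature!r}")
        scores[feature] = value
    return scores
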