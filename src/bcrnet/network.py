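"""Clonality networks: clone graph construction, clusters, dominance, SHM.

Each clone is a node whose display size scales with the cube root of its
consensus read count (so a dominant clone holding >90% of reads can share a
plot with singleton background clones). Two clones are linked when they map
to at least one equal V and at least one equal J gene and their CDR3s differ
by a single base; a connected group of such clones is a clonal cluster —
interpreted as one V(D)J rearrangement plus its somatic-hypermutation (SHM)
variants. A cluster is *dominant* when it accumulates at least a configurable
fraction (default 10%) of the chain group's reads, and a sample is labeled
monoclonal / biclonal / oligo-polyclonal by its number of dominant
heavy-chain clusters. The branching complexity of a cluster (its number of
subclones) grades the extent of SHM.

Clusters supported by a single UMI-labeled molecule are excluded before
dominance scoring: such singletons are mostly residual cDNA-synthesis, PCR
or sequencing errors that survived UMI consensus.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .assembly import Clone
from .io import UsageError

logger = logging.getLogger(__name__)

LABEL_NONE = "no_dominant_clone"
LABEL_MONO = "monoclonal"
LABEL_BI = "biclonal"
LABEL_OLIGO = "oligo_polyclonal"

#: palette for dominant clusters, assigned in descending-fraction order
DOMINANT_COLORS = ("red", "blue", "green", "orange", "purple", "cyan", "magenta")
BACKGROUND_COLOR = "gray"


def clone_key(clone: Clone) -> str:
    rec = clone.record
    return "|".join(
        (rec.chain, ",".join(sorted(rec.v_calls)), ",".join(sorted(rec.j_calls)), rec.cdr3_nt)
    )


def cdr3_distance(a: str, b: str) -> float:
    """Hamming distance for equal-length CDR3s, infinity otherwise.

    Length changes are treated as different rearrangements rather than
    indel variants: SHM is substitution-dominated, and cross-length links can
    merge unrelated clones.
    """
    if len(a) != len(b):
        return math.inf
    return sum(x != y for x, y in zip(a, b))


def _single_indel(a: str, b: str) -> bool:
    """True when one deletion turns the longer string into the shorter."""
    if abs(len(a) - len(b)) != 1:
        return False
    longer, shorter = (a, b) if len(a) > len(b) else (b, a)
    i = 0
    while i < len(shorter) and longer[i] == shorter[i]:
        i += 1
    return longer[:i] + longer[i + 1 :] == shorter


def edge_predicate(a: Clone, b: Clone, max_distance: int = 1, allow_indel: bool = False) -> bool:
    """The link rule: shared V gene, shared J gene, CDR3s within
    ``max_distance`` substitutions (optionally one indel)."""
    if not (a.record.v_calls & b.record.v_calls):
        return False
    if not (a.record.j_calls & b.record.j_calls):
        return False
    d = cdr3_distance(a.cdr3_nt, b.cdr3_nt)
    if 1 <= d <= max_distance:
        return True
    return allow_indel and _single_indel(a.cdr3_nt, b.cdr3_nt)


@dataclass
class ClonalityGraph:
    """The clone network of one chain group."""

    graph: nx.Graph
    chain_group: str
    total_reads: int
    scale: float = 1.0

    def clones(self) -> list[Clone]:
        return [attrs["clone"] for _, attrs in self.graph.nodes(data=True)]

    def subset(self, keys: Iterable[str]) -> "ClonalityGraph":
        keys = set(keys)
        sub = self.graph.subgraph(keys).copy()
        total = sum(attrs["count"] for _, attrs in sub.nodes(data=True))
        return ClonalityGraph(sub, self.chain_group, total, self.scale)


def display_size(count: int, scale: float = 1.0) -> float:
    """Node size: cube root of the read count times a display constant."""
    return scale * count ** (1.0 / 3.0)


def build_network(
    clones: list[Clone],
    chain_group: str,
    max_distance: int = 1,
    allow_indel: bool = False,
    scale: float = 1.0,
) -> ClonalityGraph:
    """Build the clonality graph of one chain group.

    Edge discovery is exact but avoids the full O(n^2) string scan by
    bucketing CDR3s by length and computing Hamming distances on byte
    matrices; cross-length buckets are only visited when indel links are
    enabled.
    """
    graph = nx.Graph()
    keys = []
    for clone in clones:
        key = clone_key(clone)
        if key in graph:
            raise ValueError(f"duplicate clonotype in network input: {key}")
        keys.append(key)
        graph.add_node(
            key,
            clone=clone,
            count=clone.count,
            fraction=clone.fraction,
            display_size=display_size(clone.count, scale),
            cdr3=clone.cdr3_nt,
            chain=clone.record.chain,
            v_calls=",".join(sorted(clone.record.v_calls)),
            j_calls=",".join(sorted(clone.record.j_calls)),
        )

    by_length: dict[int, list[int]] = {}
    for i, clone in enumerate(clones):
        by_length.setdefault(len(clone.cdr3_nt), []).append(i)

    for length, idxs in by_length.items():
        if len(idxs) < 2:
            continue
        mat = np.frombuffer(
            "".join(clones[i].cdr3_nt for i in idxs).encode(), dtype=np.uint8
        ).reshape(len(idxs), length)
        dist = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
        close = np.argwhere((dist >= 1) & (dist <= max_distance))
        for ai, bi in close:
            if ai >= bi:
                continue
            a, b = clones[idxs[ai]], clones[idxs[bi]]
            if (a.record.v_calls & b.record.v_calls) and (
                a.record.j_calls & b.record.j_calls
            ):
                graph.add_edge(keys[idxs[ai]], keys[idxs[bi]])

    if allow_indel:
        for length in by_length:
            for other in (length + 1,):
                if other not in by_length:
                    continue
                for i in by_length[length]:
                    for j in by_length[other]:
                        if edge_predicate(clones[i], clones[j], max_distance, True):
                            graph.add_edge(keys[i], keys[j])

    total = sum(c.count for c in clones)
    return ClonalityGraph(graph, chain_group, total, scale)


@dataclass
class ClonalCluster:
    """A connected component of the clonality graph: one rearrangement and
    its SHM variant subclones."""

    members: list[str]
    clones: list[Clone]
    cluster_reads: int
    fraction: float
    major_clone: Clone
    subclone_count: int
    rearrangement_key: tuple
    dominant: bool = False
    color: str = BACKGROUND_COLOR


def _make_cluster(member_keys: list[str], clones: list[Clone], total: int) -> ClonalCluster:
    reads = sum(c.count for c in clones)
    major = min(clones, key=lambda c: (-c.count, c.cdr3_nt))
    return ClonalCluster(
        members=sorted(member_keys),
        clones=clones,
        cluster_reads=reads,
        fraction=reads / total if total else 0.0,
        major_clone=major,
        subclone_count=len(clones) - 1,
        rearrangement_key=(
            ",".join(sorted(major.record.v_calls)),
            ",".join(sorted(major.record.j_calls)),
            len(major.cdr3_nt),
        ),
    )


def find_clusters(network: ClonalityGraph) -> list[ClonalCluster]:
    """Connected components of the clone graph, largest read mass first."""
    clusters = []
    for component in nx.connected_components(network.graph):
        member_keys = list(component)
        clones = [network.graph.nodes[k]["clone"] for k in member_keys]
        clusters.append(_make_cluster(member_keys, clones, network.total_reads))
    clusters.sort(key=lambda c: (-c.cluster_reads, c.members[0]))
    return clusters


def filter_singleton_clusters(
    clusters: list[ClonalCluster], min_cluster_umis: int = 2
) -> list[ClonalCluster]:
    """Drop clusters supported by fewer than ``min_cluster_umis`` molecules
    and renormalize the remaining cluster fractions."""
    kept = [c for c in clusters if c.cluster_reads >= min_cluster_umis]
    total = sum(c.cluster_reads for c in kept)
    if len(kept) < len(clusters):
        logger.info(
            "singleton-cluster filter removed %d of %d clusters",
            len(clusters) - len(kept), len(clusters),
        )
    if not kept:
        logger.warning("singleton-cluster filter removed every cluster")
    return [
        replace(c, fraction=c.cluster_reads / total if total else 0.0) for c in kept
    ]


def score_dominance(clusters: list[ClonalCluster], theta: float = 0.10) -> list[ClonalCluster]:
    """Flag clusters holding >= ``theta`` of the reads; color dominant
    clusters in descending-fraction order, the rest gray."""
    if not 0 < theta <= 1:
        raise UsageError("dominance threshold must be in (0, 1]")
    ranked = sorted(clusters, key=lambda c: (-c.fraction, c.members[0]))
    scored = {}
    n_dom = 0
    for cluster in ranked:
        if cluster.fraction >= theta:
            color = (
                DOMINANT_COLORS[n_dom]
                if n_dom < len(DOMINANT_COLORS)
                else f"dominant{n_dom + 1}"
            )
            scored[id(cluster)] = replace(cluster, dominant=True, color=color)
            n_dom += 1
        else:
            scored[id(cluster)] = replace(cluster, dominant=False, color=BACKGROUND_COLOR)
    return [scored[id(c)] for c in clusters]


def label_from_dominant_count(n_dominant: int) -> str:
    if n_dominant == 0:
        return LABEL_NONE
    if n_dominant == 1:
        return LABEL_MONO
    if n_dominant == 2:
        return LABEL_BI
    return LABEL_OLIGO


@dataclass
class GroupClassification:
    chain_group: str
    n_dominant: int
    label: str
    dominant_fractions: list[float] = field(default_factory=list)


@dataclass
class SampleClassification:
    """Per-chain-group dominance counts plus the sample-level label.

    The sample label is taken from the heavy chain (each B cell carries one
    productive heavy rearrangement; light chains are less discriminative);
    both chain labels are always reported.
    """

    per_group: dict[str, GroupClassification]
    sample_label: str | None

    def to_dict(self) -> dict:
        return {
            "sample_label": self.sample_label,
            "chain_groups": {
                g: {
                    "n_dominant": c.n_dominant,
                    "label": c.label,
                    "dominant_fractions": c.dominant_fractions,
                }
                for g, c in self.per_group.items()
            },
        }


def classify_sample(
    clusters_by_group: dict[str, list[ClonalCluster]]
) -> SampleClassification:
    """Map each chain group's dominant-cluster count to a clonality label."""
    per_group = {}
    for group, clusters in sorted(clusters_by_group.items()):
        dominant = [c for c in clusters if c.dominant]
        per_group[group] = GroupClassification(
            chain_group=group,
            n_dominant=len(dominant),
            label=label_from_dominant_count(len(dominant)),
            dominant_fractions=sorted((c.fraction for c in dominant), reverse=True),
        )
    sample_label = per_group["IGH"].label if "IGH" in per_group else None
    return SampleClassification(per_group, sample_label)


def shm_branching_metrics(cluster: ClonalCluster, network: ClonalityGraph) -> dict:
    """Branching statistics of one cluster, graded from the major clone.

    ``subclone_count`` is the number of variant clones; ``max_depth_from_major``
    the breadth-first eccentricity of the major clone within the cluster;
    ``variant_read_fraction`` the share of the cluster's reads carried by
    variants rather than the major clone.
    """
    sub = network.graph.subgraph(cluster.members)
    major_key = clone_key(cluster.major_clone)
    depths = nx.single_source_shortest_path_length(sub, major_key)
    max_depth = max(depths.values()) if depths else 0
    max_degree = max((d for _, d in sub.degree()), default=0)
    variant_fraction = (
        1.0 - cluster.major_clone.count / cluster.cluster_reads
        if cluster.cluster_reads
        else 0.0
    )
    return {
        "subclone_count": cluster.subclone_count,
        "max_depth_from_major": max_depth,
        "max_degree": max_degree,
        "variant_read_fraction": variant_fraction,
    }


def annotate_graph(network: ClonalityGraph, clusters: list[ClonalCluster]) -> None:
    """Stamp cluster membership, dominance and color onto graph nodes."""
    for i, cluster in enumerate(clusters):
        for key in cluster.members:
            if key in network.graph:
                network.graph.nodes[key].update(
                    cluster=i, dominant=cluster.dominant, color=cluster.color
                )


def clusters_to_frame(clusters: list[ClonalCluster], network: ClonalityGraph) -> pd.DataFrame:
    """Tabular cluster summary (one row per cluster)."""
    rows = []
    for i, cluster in enumerate(clusters):
        metrics = shm_branching_metrics(cluster, network)
        rows.append(
            {
                "cluster_id": i,
                "chain_group": network.chain_group,
                "n_clones": len(cluster.clones),
                "cluster_reads": cluster.cluster_reads,
                "fraction": cluster.fraction,
                "dominant": cluster.dominant,
                "color": cluster.color,
                "major_cdr3": cluster.major_clone.cdr3_nt,
                "subclone_count": metrics["subclone_count"],
                "max_depth_from_major": metrics["max_depth_from_major"],
                "variant_read_fraction": metrics["variant_read_fraction"],
            }
        )
    return pd.DataFrame(rows)
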