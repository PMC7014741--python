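"""Low-evidence filtering, read-sharing edge weights, and pre-clusters.

A contig enters the clustering only if its *effective coverage* — the summed
length of all fragments mapping to it divided by the contig length, i.e. how
many times the reads cover the full contig — is at least the threshold ``l``.
Contigs below the threshold are set aside as "low-evidence" and later emitted
as single-contig clusters.

Among passing contigs, every pair that shares at least one fragment gets an
edge with weight ``w_ij = R_ij / min(R_i, R_j)``: the fraction of the
smaller contig's fragments that the pair shares.  Weights lie in (0, 1];
weight 1 means the smaller read set is contained in the larger.  Connected
components of this graph ("pre-clusters") are the independent units of
clustering work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, NamedTuple, Sequence, Set, Tuple

import networkx as nx

from .alignment_io import ContigStats, FragmentKey, MappingTable


@dataclass(frozen=True)
class ClusteringParams:
    """The method's two user parameters.

    ``d`` — merge threshold in [0, 1]: two entities merge when the fraction
    of the smaller entity's fragments they share is ≥ d.  ``l`` — minimum
    effective coverage (fold coverage of the full contig) for a contig to
    enter clustering.
    """

    d: float = 0.3
    l: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.d <= 1.0:
            raise ValueError(f"d must lie in [0, 1], got {self.d}")
        if self.l < 0.0:
            raise ValueError(f"l must be >= 0, got {self.l}")


class WeightedEdge(NamedTuple):
    i: str
    j: str
    shared: int
    weight: float


@dataclass
class ContigGraph:
    """Read-sharing graph over passing contigs.

    ``read_sets`` stores each passing contig's fragment set — the working
    representation for all downstream weight recomputation.  Edges exist only
    for pairs with a non-zero shared count; no edge touches a low-evidence
    contig.
    """

    passing: Set[str]
    low_evidence: Set[str]
    edges: List[WeightedEdge]
    read_sets: Dict[str, Set[FragmentKey]]


@dataclass
class PreCluster:
    """A connected component of the passing subgraph with its induced edges."""

    members: FrozenSet[str]
    edges: List[WeightedEdge] = field(default_factory=list)


def effective_coverage(
    stats: ContigStats, contig_lengths: Dict[str, int], contig: str
) -> float:
    """Fold coverage of the full contig: s_i / c_i.

    For example a 750-bp contig carrying nine 250-base reads has
    (9 × 250) / 750 = 3.0.
    """
    length = contig_lengths.get(contig)
    if not length or length <= 0:
        raise ValueError(f"contig {contig!r} has no positive recorded length")
    return stats.base_sum.get(contig, 0) / length


def filter_low_evidence(
    stats: ContigStats, contig_lengths: Dict[str, int], l: float
) -> Tuple[Set[str], Set[str]]:
    """Split contigs into (passing, low_evidence) at coverage threshold l.

    A contig is low-evidence iff ``s_i < l * c_i`` (strict: a contig sitting
    exactly at the threshold passes).  At l = 0 every contig passes,
    including contigs with zero mapped reads.
    """
    if l < 0:
        raise ValueError(f"l must be >= 0, got {l}")
    passing: Set[str] = set()
    low: Set[str] = set()
    for contig, length in contig_lengths.items():
        s_i = stats.base_sum.get(contig, 0)
        if s_i < l * length:
            low.add(contig)
        else:
            passing.add(contig)
    return passing, low


def build_edges(table: MappingTable, passing: Set[str]) -> ContigGraph:
    """Compute read-sharing edges among passing contigs.

    Shared counts come from an inverted index (fragment -> contig set), so
    only pairs that actually share a fragment are ever materialized; pairs
    with R_ij = 0 are simply absent.  R_i, R_j and R_ij count distinct
    fragments pooled across samples.
    """
    unknown = passing - set(table.contig_lengths)
    if unknown:
        raise ValueError(f"passing contigs not in table: {sorted(unknown)[:5]}")
    read_sets: Dict[str, Set[FragmentKey]] = {c: set() for c in passing}
    shared: Dict[Tuple[str, str], int] = {}
    for key, contigs in table.fragment_contigs.items():
        hit = sorted(c for c in contigs if c in passing)
        for c in hit:
            read_sets[c].add(key)
        for a_idx in range(len(hit)):
            for b_idx in range(a_idx + 1, len(hit)):
                pair = (hit[a_idx], hit[b_idx])
                shared[pair] = shared.get(pair, 0) + 1
    edges = [
        WeightedEdge(i, j, n, n / min(len(read_sets[i]), len(read_sets[j])))
        for (i, j), n in sorted(shared.items())
    ]
    low = set(table.contig_lengths) - passing
    return ContigGraph(passing=set(passing), low_evidence=low, edges=edges, read_sets=read_sets)


def find_preclusters(graph: ContigGraph) -> List[PreCluster]:
    """Connected components of the passing subgraph, with induced edges.

    Isolated passing contigs come back as singleton pre-clusters.  The list
    is ordered lexicographically by each component's smallest member id.
    """
    g = nx.Graph()
    g.add_nodes_from(graph.passing)
    g.add_edges_from((e.i, e.j) for e in graph.edges)
    components = sorted(nx.connected_components(g), key=min)
    membership = {c: idx for idx, comp in enumerate(components) for c in comp}
    induced: List[List[WeightedEdge]] = [[] for _ in components]
    for e in graph.edges:
        induced[membership[e.i]].append(e)
    return [
        PreCluster(members=frozenset(comp), edges=edges)
        for comp, edges in zip(components, induced)
    ]
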