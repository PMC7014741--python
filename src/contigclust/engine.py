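"""Agglomerative clustering of pre-clusters with a self-ordering max heap.

Each pre-cluster is clustered independently (and therefore parallelizably).
Live entities start as single contigs; at each iteration the highest-weight
valid heap entry is popped and, if its weight is at least the threshold
``d``, the two entities merge (members and read sets are unioned) and weights
between the new entity and every other live entity are recomputed exactly
over the fragment-set unions and re-pushed.  Clustering stops when the best
valid entry falls below ``d`` or a single entity remains.

Stale heap entries — those referring to an entity consumed by an earlier
merge — are discarded lazily on pop (each entity id is used once, so an entry
is valid iff both its entity ids are still live).  Ties on weight break
deterministically by (smaller min entity id, then smaller max entity id);
initial ids follow the lexicographic order of the member contigs, so repeated
runs and any worker count give identical output.
"""

from __future__ import annotations

import heapq
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .alignment_io import FragmentKey, MappingTable
from .graph import ClusteringParams, ContigGraph, PreCluster, find_preclusters

CLUSTERED = "clustered"
SINGLETON = "singleton"
LOW_EVIDENCE = "low_evidence"


@dataclass
class ClusterEntity:
    """A live entity during agglomeration: one or more contigs and the union
    of their fragment sets."""

    entity_id: int
    members: Set[str]
    read_set: Set[FragmentKey]
    version: int = 0


@dataclass
class ClusterSet:
    """Final partition of all input contigs.

    ``clusters`` maps cluster id -> member contigs; ``types`` labels each
    cluster ``clustered`` (≥ 2 members), ``singleton`` (one passing contig)
    or ``low_evidence``.  ``per_sample_counts`` holds the raw count of each
    cluster per sample: the number of distinct fragments of that sample
    mapping to any member contig (a fragment mapping into two final clusters
    is counted in both).
    """

    clusters: List[Tuple[str, FrozenSet[str]]]
    types: Dict[str, str]
    per_sample_counts: Dict[str, Dict[str, int]]
    samples: List[str] = field(default_factory=list)

    @property
    def z(self) -> int:
        """Total number of output entities."""
        return len(self.clusters)

    def as_mapping(self) -> Dict[str, str]:
        """contig id -> cluster id over every input contig."""
        return {c: cid for cid, members in self.clusters for c in members}


def entity_weight(a: ClusterEntity, b: ClusterEntity) -> float:
    """Shared fragments over the smaller entity's fragment count."""
    if not a.read_set or not b.read_set:
        raise ValueError("entity weight undefined for an empty read set")
    shared = len(a.read_set & b.read_set)
    return shared / min(len(a.read_set), len(b.read_set))


def cluster_precluster(
    pc: PreCluster,
    read_sets: Dict[str, Set[FragmentKey]],
    d: float,
) -> List[ClusterEntity]:
    """Agglomerate one pre-cluster at threshold d; returns surviving entities.

    At d = 0 the whole pre-cluster collapses to one entity (every positive
    edge merges and merging preserves connectivity); at d = 1 only entities
    whose smaller read set is contained in the larger ever merge.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"d must lie in [0, 1], got {d}")
    order = sorted(pc.members)
    entities: Dict[int, ClusterEntity] = {
        idx: ClusterEntity(idx, {contig}, set(read_sets[contig]))
        for idx, contig in enumerate(order)
    }
    contig_entity = {contig: idx for idx, contig in enumerate(order)}
    next_id = len(order)
    generation = 0

    heap: List[Tuple[float, int, int]] = []
    for e in pc.edges:
        a, b = contig_entity[e.i], contig_entity[e.j]
        heap.append((-e.weight, min(a, b), max(a, b)))
    heapq.heapify(heap)

    while heap and len(entities) > 1:
        neg_w, a_id, b_id = heapq.heappop(heap)
        if a_id not in entities or b_id not in entities:
            continue  # stale: one side was consumed by an earlier merge
        if -neg_w < d:
            break  # best valid weight below threshold: heap content is final
        a = entities.pop(a_id)
        b = entities.pop(b_id)
        generation += 1
        merged = ClusterEntity(
            next_id, a.members | b.members, a.read_set | b.read_set, version=generation
        )
        next_id += 1
        for other_id, other in entities.items():
            w = entity_weight(merged, other)
            if w > 0:
                heapq.heappush(
                    heap,
                    (-w, min(merged.entity_id, other_id), max(merged.entity_id, other_id)),
                )
        entities[merged.entity_id] = merged

    return sorted(entities.values(), key=lambda e: min(e.members))


def _contig_fragment_index(table: MappingTable) -> Dict[str, Set[FragmentKey]]:
    index: Dict[str, Set[FragmentKey]] = {}
    for key, contigs in table.fragment_contigs.items():
        for contig in contigs:
            index.setdefault(contig, set()).add(key)
    return index


def _cluster_counts(
    members: FrozenSet[str],
    index: Dict[str, Set[FragmentKey]],
    samples: Sequence[str],
) -> Dict[str, int]:
    counts = {s: 0 for s in samples}
    fragments: Set[FragmentKey] = set()
    for contig in members:
        fragments |= index.get(contig, set())
    for sample, _ in fragments:
        counts[sample] = counts.get(sample, 0) + 1
    return counts


def cluster_all(
    graph: ContigGraph,
    params: ClusteringParams,
    table: Optional[MappingTable] = None,
    workers: int = 1,
) -> ClusterSet:
    """Cluster every pre-cluster and assemble the final partition.

    Pre-clusters are processed independently; the result is identical for
    any ``workers`` value.  Isolated passing contigs become ``singleton``
    clusters and filtered contigs ``low_evidence`` single-contig clusters,
    so the output partitions the full assembly.  Cluster ids are assigned in
    lexicographic order of each cluster's smallest member contig.  Per-sample
    distinct-fragment counts are computed when the mapping ``table`` is
    supplied (low-evidence contigs' fragments are not in the graph).
    """
    preclusters = find_preclusters(graph)

    def run(pc: PreCluster) -> List[ClusterEntity]:
        return cluster_precluster(pc, graph.read_sets, params.d)

    if workers > 1 and len(preclusters) > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(run, preclusters))
    else:
        results = [run(pc) for pc in preclusters]

    raw: List[Tuple[FrozenSet[str], str]] = []
    for entities in results:
        for ent in entities:
            kind = CLUSTERED if len(ent.members) > 1 else SINGLETON
            raw.append((frozenset(ent.members), kind))
    for contig in sorted(graph.low_evidence):
        raw.append((frozenset({contig}), LOW_EVIDENCE))

    raw.sort(key=lambda item: min(item[0]))
    width = max(6, len(str(len(raw))))
    samples = list(table.samples) if table is not None else []
    index = _contig_fragment_index(table) if table is not None else {}

    clusters: List[Tuple[str, FrozenSet[str]]] = []
    types: Dict[str, str] = {}
    counts: Dict[str, Dict[str, int]] = {}
    for idx, (members, kind) in enumerate(raw):
        cid = f"CL{idx:0{width}d}"
        clusters.append((cid, members))
        types[cid] = kind
        counts[cid] = _cluster_counts(members, index, samples)
    return ClusterSet(
        clusters=clusters, types=types, per_sample_counts=counts, samples=samples
    )
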