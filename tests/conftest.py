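"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random
from typing import Dict, FrozenSet, List, Set, Tuple

import pytest

from contigclust.alignment_io import MappingTable, compute_contig_stats
from contigclust.graph import ContigGraph, build_edges, filter_low_evidence, find_preclusters


def make_table(
    fragment_contigs: Dict[str, Set[str]],
    contig_lengths: Dict[str, int],
    fragment_length: int = 100,
    sample: str = "s1",
) -> MappingTable:
    """Build a single-sample MappingTable directly from a fragment->contigs map."""
    table = MappingTable(contig_lengths=dict(contig_lengths), samples=[sample])
    for fid, contigs in fragment_contigs.items():
        table.fragment_contigs[(sample, fid)] = set(contigs)
        table.fragment_lengths[(sample, fid)] = fragment_length
    return table


def abc_table() -> MappingTable:
    """Three contigs with read sets A={f1..f10}, B={f6..f15}, C={f14,f15,f16..f20}.

    w(A,B) = 5/10 = 0.5, w(B,C) = 2/7, w(A,C) = 0.
    """
    frags: Dict[str, Set[str]] = {}
    for i in range(1, 21):
        fid = f"f{i:02d}"
        contigs = set()
        if 1 <= i <= 10:
            contigs.add("A")
        if 6 <= i <= 15:
            contigs.add("B")
        if i in (14, 15) or 16 <= i <= 20:
            contigs.add("C")
        frags[fid] = contigs
    return make_table(frags, {"A": 300, "B": 300, "C": 200})


@pytest.fixture
def abc_graph() -> Tuple[MappingTable, ContigGraph]:
    table = abc_table()
    stats = compute_contig_stats(table)
    passing, _ = filter_low_evidence(stats, table.contig_lengths, 0.0)
    return table, build_edges(table, passing)


def random_instance(
    rng: random.Random,
    max_contigs: int = 30,
    max_fragments: int = 500,
) -> MappingTable:
    """A random multi-mapping table for oracle-equivalence tests."""
    n_contigs = rng.randint(2, max_contigs)
    n_fragments = rng.randint(n_contigs, max_fragments)
    contigs = [f"c{k:03d}" for k in range(n_contigs)]
    lengths = {c: rng.randint(100, 2000) for c in contigs}
    frags: Dict[str, Set[str]] = {}
    for f in range(n_fragments):
        k = rng.choice([1, 1, 1, 2, 2, 3])
        frags[f"f{f:04d}"] = set(rng.sample(contigs, min(k, n_contigs)))
    return make_table(frags, lengths)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def naive_cluster_precluster(
    members: FrozenSet[str],
    read_sets: Dict[str, Set[Tuple[str, str]]],
    d: float,
) -> List[FrozenSet[str]]:
    """Re-sort-every-iteration agglomeration over one pre-cluster.

    Recomputes every pairwise entity weight each round and fully sorts the
    candidate list, using the same tie rule as the engine: largest weight
    first, ties to (smaller min entity id, smaller max entity id), initial
    ids in lexicographic contig order, merged entities taking fresh ids.
    """
    order = sorted(members)
    ents: Dict[int, Tuple[Set[str], Set]] = {
        idx: ({c}, set(read_sets[c])) for idx, c in enumerate(order)
    }
    next_id = len(order)
    while len(ents) > 1:
        candidates = []
        ids = sorted(ents)
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                i, j = ids[x], ids[y]
                ra, rb = ents[i][1], ents[j][1]
                w = len(ra & rb) / min(len(ra), len(rb))
                candidates.append((-w, i, j))
        candidates.sort()
        neg_w, i, j = candidates[0]
        if -neg_w < d:
            break
        mi, ri = ents.pop(i)
        mj, rj = ents.pop(j)
        ents[next_id] = (mi | mj, ri | rj)
        next_id += 1
    return [frozenset(m) for m, _ in ents.values()]


def naive_partition(graph: ContigGraph, d: float) -> Set[FrozenSet[str]]:
    """Full-partition oracle: naive agglomeration per pre-cluster plus
    low-evidence singletons, as a set of frozensets of contig ids."""
    clusters: Set[FrozenSet[str]] = set()
    for pc in find_preclusters(graph):
        for cluster in naive_cluster_precluster(pc.members, graph.read_sets, d):
            clusters.add(cluster)
    for contig in graph.low_evidence:
        clusters.add(frozenset({contig}))
    return clusters


def brute_force_confusion(
    partition: Dict[str, str], truth: Dict[str, str]
) -> Tuple[int, int, int, int]:
    """Enumerate all labeled contig pairs and tally (a, b, c, d)."""
    keys = sorted(partition.keys() & truth.keys())
    a = b = c = d = 0
    for x in range(len(keys)):
        for y in range(x + 1, len(keys)):
            same_cluster = partition[keys[x]] == partition[keys[y]]
            same_locus = truth[keys[x]] == truth[keys[y]]
            if same_cluster and same_locus:
                a += 1
            elif same_cluster:
                b += 1
            elif same_locus:
                c += 1
            else:
                d += 1
    return a, b, c, d


def engine_partition(graph: ContigGraph, d: float, l: float = 0.0):
    """Run the real engine and return the partition as a set of frozensets."""
    from contigclust.engine import cluster_all
    from contigclust.graph import ClusteringParams

    cs = cluster_all(graph, ClusteringParams(d=d, l=l))
    return {members for _, members in cs.clusters}
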