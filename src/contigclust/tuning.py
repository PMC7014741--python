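"""Threshold tuning: d-sweeps, knee detection, and target cluster counts.

For a fixed assembly the cluster count z = f(c, d) is a non-decreasing step
function of the merge threshold d, with z_min = f(c, 0) (each pre-cluster
collapses to one cluster) and z_max = f(c, 1) (only subset read-sets merge).
Two cheap runs at the extremes expose the dynamic range [z_min, z_max].

When an external identification of contigs is available (e.g. BLAST hits of
each contig against a reference transcriptome), the sweep can additionally
track n_As — the number of distinct external sequences identified among the
representatives at each d — and the clustering efficiency Ef = n_As / z.
Empirically z(d) is steep near both ends and flat in the middle; the knees
d_l (near 0) and d_r (near 1) are located here by the extreme discrete
second difference of z(d), and the d maximizing Ef is a natural operating
point ("not too few, not too many" clusters).

A target cluster count z* in [z_min, z_max] can be inverted to a threshold
d* by bisection, exploiting monotonicity of f(c, d).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .alignment_io import ContigStats, MappingTable
from .engine import ClusterSet, cluster_all
from .graph import ClusteringParams, ContigGraph
from .outputs import select_representatives


@dataclass
class SweepPoint:
    d: float
    z: int
    n_As: Optional[int] = None
    Ef: Optional[float] = None


@dataclass
class SweepCurve:
    """(d, z[, n_As, Ef]) records over a threshold grid, sorted by d."""

    points: List[SweepPoint]
    z_min: int
    z_max: int
    d_l: Optional[float] = None
    d_r: Optional[float] = None
    d_maxEf: Optional[float] = None
    no_knee: bool = False
    #: full cluster set at each swept d, for downstream efficiency curves
    cluster_sets: Dict[float, ClusterSet] = field(default_factory=dict)


def sweep_d(
    graph: ContigGraph,
    d_grid: Sequence[float],
    params: ClusteringParams,
    table: Optional[MappingTable] = None,
    workers: int = 1,
) -> SweepCurve:
    """Run the clustering at every d in the grid and record z(d).

    The endpoints 0 and 1 are always included; z_min and z_max are taken
    from them.  A non-monotone z across the grid would contradict the
    refinement property of the agglomeration and is raised as an internal
    error.
    """
    grid = sorted(set(float(d) for d in d_grid) | {0.0, 1.0})
    for d in grid:
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"grid value {d} outside [0, 1]")
    points: List[SweepPoint] = []
    cluster_sets: Dict[float, ClusterSet] = {}
    for d in grid:
        cs = cluster_all(
            graph, ClusteringParams(d=d, l=params.l), table=table, workers=workers
        )
        cluster_sets[d] = cs
        points.append(SweepPoint(d=d, z=cs.z))
    for prev, cur in zip(points, points[1:]):
        if cur.z < prev.z:
            raise RuntimeError(
                f"z decreased from {prev.z} (d={prev.d}) to {cur.z} (d={cur.d}); "
                "this indicates a clustering engine defect"
            )
    return SweepCurve(
        points=points,
        z_min=points[0].z,
        z_max=points[-1].z,
        cluster_sets=cluster_sets,
    )


def efficiency_curve(
    curve: SweepCurve,
    id_map: Dict[str, str],
    contig_lengths: Dict[str, int],
    stats: ContigStats,
    reps_rule: str = "longest",
    over_clusters: bool = False,
) -> SweepCurve:
    """Annotate a sweep with n_As and Ef = n_As / z at every point.

    ``id_map`` gives at most one external id per contig (e.g. from a BLAST
    run performed by the user).  n_As counts distinct external ids among the
    representative contigs of that run (``reps_rule`` "longest" or
    "most_reads"); with ``over_clusters=True`` ids are counted over whole
    clusters instead.  The d with maximal Ef is stored as ``d_maxEf``
    (ties to the smaller d).
    """
    best: Optional[Tuple[float, float]] = None
    for point in curve.points:
        cs = curve.cluster_sets.get(point.d)
        if cs is None:
            raise ValueError(f"no cluster set recorded for d={point.d}")
        if over_clusters:
            ids = {
                id_map[c]
                for _, members in cs.clusters
                for c in members
                if c in id_map
            }
        else:
            reps = select_representatives(cs, contig_lengths, stats)
            if reps_rule == "longest":
                chosen = (r.longest_member for r in reps)
            elif reps_rule == "most_reads":
                chosen = (r.most_reads_member for r in reps)
            else:
                raise ValueError(f"unknown representative rule {reps_rule!r}")
            ids = {id_map[c] for c in chosen if c in id_map}
        point.n_As = len(ids)
        point.Ef = len(ids) / cs.z if cs.z else 0.0
        if best is None or point.Ef > best[1]:
            best = (point.d, point.Ef)
    curve.d_maxEf = best[0] if best is not None else None
    return curve


def find_knees(curve: SweepCurve) -> Tuple[float, float]:
    """Locate the left and right knees of z(d) by discrete second difference.

    Forward slopes s_k between consecutive grid points are differenced; d_l
    is the interior grid point in the left half with the largest slope drop
    (most negative second difference, ties to the smaller d) and d_r the
    point in the right half with the largest slope rise (ties to the larger
    d).  A flat or perfectly linear curve has no knee: ``no_knee`` is set
    and (smallest d, largest d) returned.
    """
    pts = curve.points
    if len(pts) < 4:
        raise ValueError("knee detection needs at least 4 grid points")
    ds = [p.d for p in pts]
    zs = [p.z for p in pts]
    slopes = [
        (z1 - z0) / (d1 - d0)
        for (d0, z0), (d1, z1) in zip(zip(ds, zs), zip(ds[1:], zs[1:]))
    ]
    # second difference at interior point k uses slopes on both sides
    second = [slopes[k] - slopes[k - 1] for k in range(1, len(slopes))]
    interior = ds[1:-1]
    if all(s == 0 for s in second):
        curve.no_knee = True
        curve.d_l, curve.d_r = ds[0], ds[-1]
        return ds[0], ds[-1]
    mid = (ds[0] + ds[-1]) / 2.0
    left = [(d, s) for d, s in zip(interior, second) if d <= mid]
    right = [(d, s) for d, s in zip(interior, second) if d >= mid]
    if left:
        d_l = min(left, key=lambda item: (item[1], item[0]))[0]
    else:
        d_l = ds[0]
    if right:
        d_r = max(right, key=lambda item: (item[1], item[0]))[0]
    else:
        d_r = ds[-1]
    curve.no_knee = False
    curve.d_l, curve.d_r = d_l, d_r
    return d_l, d_r


def solve_for_target_z(
    graph: ContigGraph,
    z_star: int,
    tolerance: int,
    params: ClusteringParams,
    table: Optional[MappingTable] = None,
) -> float:
    """Find d* with f(c, d*) ≈ z* by bisection on the monotone step function.

    Evaluations are memoized; the bracket is narrowed until it is < 1e-3
    wide or an evaluated point is within ``tolerance`` clusters of z*.
    Among evaluated points the one minimizing |f − z*| (ties to smaller d)
    is returned.  z* outside [z_min, z_max] is a domain error.
    """
    cache: Dict[float, int] = {}

    def f(d: float) -> int:
        if d not in cache:
            cache[d] = cluster_all(
                graph, ClusteringParams(d=d, l=params.l), table=table
            ).z
        return cache[d]

    z_min, z_max = f(0.0), f(1.0)
    if not z_min <= z_star <= z_max:
        raise ValueError(f"target z={z_star} outside dynamic range [{z_min}, {z_max}]")
    if z_star == z_min:
        return 0.0
    if z_star == z_max:
        return 1.0

    lo, hi = 0.0, 1.0
    while hi - lo >= 1e-3:
        mid = (lo + hi) / 2.0
        z_mid = f(mid)
        if abs(z_mid - z_star) <= tolerance:
            break
        if z_mid < z_star:
            lo = mid
        else:
            hi = mid
    best = min(cache.items(), key=lambda item: (abs(item[1] - z_star), item[0]))
    return best[0]
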