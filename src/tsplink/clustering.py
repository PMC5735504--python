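"""Decomposition of markers into candidate linkage groups.

The strategy is deliberate over-segmentation followed by merging: the
minimum spanning tree of the rf graph is cut at its largest rf edges
(1.5 x the expected chromosome number k, growing one cut at a time until
at least k *significant* clusters exist), and each resulting cluster is
then run through the heuristic path solver and broken wherever two
path-adjacent markers show an rf jump above a threshold.  A cluster is
significant when it holds at least s = m / (2k) markers -- small enough
to tolerate uneven chromosome sizes, large enough to ignore debris.

Merging the over-cut pieces back together is the job of
:mod:`tsplink.merging`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ValidationError
from .recombination import RFMatrix
from .tsp import DEFAULT_EXACT_LIMIT, DEFAULT_SCALE, build_weight_matrix, solve_heuristic

CLUSTER_STAGES = ("initial", "split", "merged")


@dataclass
class ClusterSet:
    """A partition of marker indices into candidate linkage groups."""

    clusters: list[list[int]]
    stage: str = "initial"

    def __post_init__(self) -> None:
        if self.stage not in CLUSTER_STAGES:
            raise ValidationError(f"unknown cluster stage {self.stage!r}")
        seen: set[int] = set()
        for cl in self.clusters:
            if seen & set(cl):
                raise ValidationError("clusters are not disjoint")
            seen |= set(cl)

    def all_markers(self) -> set[int]:
        return {i for cl in self.clusters for i in cl}

    def sizes(self) -> list[int]:
        return [len(cl) for cl in self.clusters]


@dataclass
class PipelineParams:
    """Tunable knobs for the whole map-construction pipeline.

    k is the user's prior on the chromosome number and the only parameter
    without a usable default.  rf values above ``cutoff`` are inflated to
    0.5 before any graph work.  ``cut_multiplier`` controls the initial
    over-cutting of the spanning tree; ``break_threshold`` is the largest
    rf tolerated between path-adjacent markers inside one cluster and
    doubles as the guard that vetoes merges re-introducing such a jump;
    ``direct_threshold`` is the rf below which a cluster pair may merge
    on matrix evidence alone.  Solver budgets are split between a cheap
    tier used while clustering/merging and a high tier for final
    ordering.
    """

    k: int
    cutoff: float = 0.4
    cut_multiplier: float = 1.5
    break_threshold: float = 0.35
    direct_threshold: float = 0.15
    stage_ratio: float = 0.5  # "less than half of the next smallest" tests
    scale: int = DEFAULT_SCALE
    exact_limit: int = DEFAULT_EXACT_LIMIT
    cluster_restarts: int = 2
    order_restarts: int = 8
    order_perturbations: int = 150
    merge_candidates: int = 3
    map_function: str = "haldane"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        for name in ("cutoff", "break_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 0.5:
                raise ParameterError(f"{name} must be in (0, 0.5], got {v}")
        if not 0.0 < self.direct_threshold <= 0.5:
            raise ParameterError("direct_threshold must be in (0, 0.5]")
        if self.cut_multiplier < 1.0:
            raise ParameterError("cut_multiplier must be >= 1")


def min_cluster_size(m: int, k: int) -> float:
    """Significance threshold s = m / (2k); clusters of size >= s count."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    if m < 1:
        raise ParameterError("m must be >= 1")
    return m / (2.0 * k)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        p = self.parent
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_mst(r: RFMatrix) -> list[tuple[int, int, float]]:
    """Minimum spanning tree of the complete rf graph (Kruskal).

    Returns the m-1 edges in the order they were accepted, i.e. sorted
    ascending by (rf, smaller index, larger index) -- the documented
    deterministic tie-break.
    """
    m = r.n_markers
    if m == 1:
        return []
    iu = np.triu_indices(m, k=1)
    vals = r.rf[iu]
    order = np.lexsort((iu[1], iu[0], vals))
    uf = _UnionFind(m)
    edges: list[tuple[int, int, float]] = []
    ii, jj = iu[0][order], iu[1][order]
    vv = vals[order]
    for a, b, v in zip(ii, jj, vv):
        if uf.union(int(a), int(b)):
            edges.append((int(a), int(b), float(v)))
            if len(edges) == m - 1:
                break
    return edges


def _components(m: int, edges: list[tuple[int, int, float]]) -> list[list[int]]:
    uf = _UnionFind(m)
    for a, b, _ in edges:
        uf.union(a, b)
    groups: dict[int, list[int]] = {}
    for i in range(m):
        groups.setdefault(uf.find(i), []).append(i)
    # deterministic output order: by smallest member
    return sorted(groups.values(), key=lambda cl: cl[0])


def initial_clusters(r: RFMatrix, params: PipelineParams) -> ClusterSet:
    """Cut the MST at its largest rf edges until >= k significant clusters.

    The first ceil(cut_multiplier * k) largest-rf edges are removed; if
    that leaves fewer than k components of size >= s = m/(2k), the
    next-largest surviving edge is cut, and so on until enough
    significant components exist or the tree is exhausted.  All
    components, including sub-significant debris, are returned: merging
    decides their fate later.
    """
    m = r.n_markers
    if m < params.k:
        raise ParameterError(f"{m} markers cannot form {params.k} linkage groups")
    s = min_cluster_size(m, params.k)
    edges = build_mst(r)
    if edges and max(e[2] for e in edges) == 0.0:
        warnings.warn("all MST edges have rf 0; markers form one degenerate cluster")
    # largest first; ties broken by (index, index) for determinism
    by_size = sorted(edges, key=lambda e: (-e[2], e[0], e[1]))
    n_cut0 = min(math.ceil(params.cut_multiplier * params.k), len(by_size))

    # Walk candidate cut counts by *adding edges back* smallest-rf first, so
    # the significant-cluster count at every cut depth comes from one linear
    # union-find sweep.  significant[c] = number of components of size >= s
    # when the c largest edges are removed.
    uf = _UnionFind(m)
    size = [1] * m
    n_sig = m if s <= 1 else 0
    significant = [0] * (len(by_size) + 1)
    significant[len(by_size)] = n_sig
    for c in range(len(by_size) - 1, -1, -1):
        a, b, _v = by_size[c]
        ra, rb = uf.find(a), uf.find(b)
        sa, sb = size[ra], size[rb]
        uf.union(ra, rb)
        size[uf.find(ra)] = sa + sb
        n_sig += int(sa + sb >= s) - int(sa >= s) - int(sb >= s)
        significant[c] = n_sig

    # the spec'd iteration: start at n_cut0, add one cut at a time until at
    # least k significant clusters exist.  When no cut depth ever reaches k
    # (over-cutting can only shrink components, so the count may stall),
    # fall back to the depth with the most significant clusters instead of
    # shattering the tree, and warn.
    candidates = range(n_cut0, len(by_size) + 1)
    n_cut = next((c for c in candidates if significant[c] >= params.k), None)
    if n_cut is None:
        n_cut = max(candidates, key=lambda c: (significant[c], -c))
        warnings.warn(
            f"cutting never produced {params.k} significant clusters; "
            f"using {n_cut} cuts ({significant[n_cut]} significant)"
        )
    comps = _components(m, by_size[n_cut:])
    return ClusterSet(clusters=comps, stage="initial")


def split_cluster_by_path(
    cluster: list[int],
    r: RFMatrix,
    break_threshold: float,
    seed: int = 0,
    scale: int = DEFAULT_SCALE,
    restarts: int = 2,
) -> list[list[int]]:
    """Break a cluster wherever its heuristic path jumps above the threshold.

    A cluster spanning two chromosomes cannot avoid at least one adjacent
    pair with rf near 0.5 in its best path; cutting every adjacency above
    ``break_threshold`` separates the contaminants (singletons allowed).
    A cluster from a single chromosome passes through unchanged.
    """
    if len(cluster) <= 1:
        return [list(cluster)]
    w = build_weight_matrix(r, cluster, scale=scale)
    path = solve_heuristic(w, seed=seed, restarts=restarts)
    breaks = np.nonzero(path.edge_rf > break_threshold)[0]
    segments: list[list[int]] = []
    start = 0
    for b in breaks:
        segments.append(path.order[start : b + 1].tolist())
        start = b + 1
    segments.append(path.order[start:].tolist())
    return segments


def split_clusters(
    cs: ClusterSet, r: RFMatrix, params: PipelineParams
) -> ClusterSet:
    """Apply :func:`split_cluster_by_path` to every cluster of ``cs``."""
    out: list[list[int]] = []
    for idx, cl in enumerate(cs.clusters):
        out.extend(
            split_cluster_by_path(
                cl,
                r,
                params.break_threshold,
                seed=params.seed + idx,
                scale=params.scale,
                restarts=params.cluster_restarts,
            )
        )
    out = sorted(out, key=lambda c: min(c))
    return ClusterSet(clusters=out, stage="split")


def clusters_to_frame(cs: ClusterSet, marker_names: list[str]):
    """Dump a ClusterSet as a tidy (marker, cluster_id, stage) table."""
    import pandas as pd

    rows = [
        {"marker": marker_names[i], "cluster_id": cid, "stage": cs.stage}
        for cid, cl in enumerate(cs.clusters)
        for i in cl
    ]
    return pd.DataFrame(rows)
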