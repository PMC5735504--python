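"""Hamiltonian-path solvers over rf weight matrices.

Marker ordering is a minimum-weight Hamiltonian path problem: markers
are vertices, pairwise rf values are edge weights, and the best linear
order minimises the summed rf along the path.  A path problem is turned
into a standard (cyclic) TSP by appending a *dummy vertex* with
zero-weight edges to every marker: the optimal tour must pass through
the dummy, and cutting the tour there yields the optimal open path
without ever paying for the long edge between the two chromosome ends.

Two solver tiers are provided, mirroring the heuristic/exact split used
throughout the pipeline:

* :func:`solve_heuristic` -- nearest-neighbour construction followed by
  best-improvement 2-opt and Or-opt local search (with optional
  multi-start and double-bridge perturbation chains).  Used during
  clustering and merging, where speed matters and the path is only
  inspected for large rf jumps.
* :func:`solve_exact_small` -- Held-Karp dynamic programming over vertex
  subsets; provably optimal but exponential, so limited to small
  instances.  Used for the final ordering of small linkage groups; for
  larger groups the heuristic with a high search budget stands in, and
  "optimal" is then best-found under a fixed, seeded budget.

Weights are integers (rf scaled by ``scale``, default 1e5), the usual
contract of TSP codes; a TSPLIB writer is included so external solvers
can be plugged in, but nothing in the pipeline requires one.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError, SizeError, ValidationError
from .recombination import RFMatrix

DEFAULT_SCALE = 100_000
#: Held-Karp ceiling, counted in vertices including the dummy
DEFAULT_EXACT_LIMIT = 18

_INF = np.int64(1) << 50


@dataclass
class WeightMatrix:
    """Integer TSP weight matrix over a marker subset plus the dummy vertex."""

    weights: np.ndarray  # int64, (size, size), symmetric, zero diagonal
    dummy_index: int
    scale: int
    subset: np.ndarray  # global marker indices, length size - 1

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.int64)
        self.subset = np.asarray(self.subset, dtype=np.int64)
        w = self.weights
        if w.shape[0] != w.shape[1]:
            raise ValidationError("weight matrix must be square")
        if np.any(w != w.T) or np.any(np.diag(w) != 0) or w.min() < 0:
            raise ValidationError("weights must be symmetric, non-negative, zero-diagonal")
        if np.any(w[self.dummy_index] != 0):
            raise ValidationError("dummy vertex must have all-zero weights")

    @property
    def size(self) -> int:
        return self.weights.shape[0]

    @property
    def n_markers(self) -> int:
        return self.size - 1


@dataclass
class MarkerPath:
    """An ordered run of markers with the rf of each adjacent step."""

    order: np.ndarray  # global marker indices
    edge_rf: np.ndarray  # length len(order) - 1
    cost: float
    solver: str = "heuristic"

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=np.int64)
        self.edge_rf = np.asarray(self.edge_rf, dtype=np.float64)
        if len(set(self.order.tolist())) != len(self.order):
            raise ValidationError("path visits a marker twice")
        if len(self.edge_rf) != max(len(self.order) - 1, 0):
            raise ValidationError("edge_rf length mismatch")
        if abs(self.cost - float(self.edge_rf.sum())) > 1e-9:
            raise ValidationError("cost does not match edge_rf sum")

    def reversed(self) -> "MarkerPath":
        return MarkerPath(self.order[::-1].copy(), self.edge_rf[::-1].copy(),
                          self.cost, self.solver)


def build_weight_matrix(
    r: RFMatrix, subset, scale: int = DEFAULT_SCALE
) -> WeightMatrix:
    """Integer weight matrix for a marker subset, dummy vertex appended last."""
    subset = np.asarray(subset, dtype=np.int64)
    if subset.size == 0:
        raise ParameterError("subset must be non-empty")
    if len(set(subset.tolist())) != subset.size:
        raise ParameterError("subset contains duplicate marker indices")
    if scale < 1:
        raise ParameterError("scale must be >= 1")
    n = subset.size
    w = np.zeros((n + 1, n + 1), dtype=np.int64)
    w[:n, :n] = np.rint(scale * r.rf[np.ix_(subset, subset)]).astype(np.int64)
    return WeightMatrix(weights=w, dummy_index=n, scale=scale, subset=subset)


def _path_from_local(w: WeightMatrix, local_order: np.ndarray, solver: str) -> MarkerPath:
    markers = w.weights[:-1, :-1]
    if len(local_order) > 1:
        edges = markers[local_order[:-1], local_order[1:]] / w.scale
    else:
        edges = np.empty(0)
    return MarkerPath(
        order=w.subset[local_order],
        edge_rf=edges,
        cost=float(edges.sum()),
        solver=solver,
    )


def _int_path_cost(markers: np.ndarray, order: np.ndarray) -> int:
    if len(order) < 2:
        return 0
    return int(markers[order[:-1], order[1:]].sum())


# ---------------------------------------------------------------------------
# heuristic tier
# ---------------------------------------------------------------------------

def _nearest_neighbour(markers: np.ndarray, start: int) -> np.ndarray:
    n = markers.shape[0]
    order = np.empty(n, dtype=np.int64)
    order[0] = start
    remaining = np.ones(n, dtype=bool)
    remaining[start] = False
    cur = start
    row = markers.astype(np.float64)
    for i in range(1, n):
        cand = np.where(remaining, row[cur], np.inf)
        cur = int(np.argmin(cand))
        order[i] = cur
        remaining[cur] = False
    return order


def _two_opt_move(wd: np.ndarray, x: np.ndarray, dummy: int):
    """Best segment-reversal move on an open path; returns (delta, i, j) or None.

    Endpoint edges are free (they attach to the dummy), so reversals that
    relocate a path end are considered automatically.
    """
    n = len(x)
    ext = np.concatenate(([dummy], x, [dummy]))
    left = ext[:n]  # predecessor of position i (dummy before position 0)
    right = ext[2:]  # successor of position j
    t1 = wd[left][:, x]  # wd[pred(i), x[j]]
    t2 = wd[x][:, right]  # wd[x[i], succ(j)]
    vi = wd[left, x]
    vj = wd[x, right]
    delta = t1 + t2 - vi[:, None] - vj[None, :]
    delta[np.tril_indices(n)] = _INF  # need i < j
    flat = int(np.argmin(delta))
    i, j = divmod(flat, n)
    d = int(delta[i, j])
    if d < 0:
        return d, i, j
    return None


def _or_opt_move(wd: np.ndarray, x: np.ndarray, dummy: int, seg_len: int):
    """Best relocation of a length-``seg_len`` segment (either orientation)."""
    n = len(x)
    if n <= seg_len:
        return None
    ext = np.concatenate(([dummy], x, [dummy]))
    starts = np.arange(n - seg_len + 1)
    s_first = x[starts]
    s_last = x[starts + seg_len - 1]
    pred = ext[starts]
    succ = ext[starts + seg_len + 1]
    gain = wd[pred, s_first] + wd[s_last, succ] - wd[pred, succ]
    # candidate insertion edges (u_p, v_p), p = 0..n (includes dummy ends)
    u = ext[: n + 1]
    v = ext[1 : n + 2]
    base = wd[u, v]
    ins_f = wd[u][:, s_first].T + wd[v][:, s_last].T - base[None, :]
    ins_r = wd[u][:, s_last].T + wd[v][:, s_first].T - base[None, :]
    delta_f = ins_f - gain[:, None]
    delta_r = ins_r - gain[:, None]
    # edges inside or bounding the segment are not valid insertion points
    p_idx = np.arange(n + 1)[None, :]
    invalid = (p_idx >= starts[:, None]) & (p_idx <= starts[:, None] + seg_len)
    delta_f[invalid] = _INF
    delta_r[invalid] = _INF
    best_f = int(np.argmin(delta_f))
    best_r = int(np.argmin(delta_r))
    cand = []
    i, p = divmod(best_f, n + 1)
    cand.append((int(delta_f[i, p]), i, p, False))
    i, p = divmod(best_r, n + 1)
    cand.append((int(delta_r[i, p]), i, p, True))
    d, i, p, rev = min(cand, key=lambda t: t[0])
    if d < 0:
        return d, int(i), int(p), rev
    return None


def _apply_or_opt(x: np.ndarray, i: int, p: int, seg_len: int, rev: bool) -> np.ndarray:
    seg = x[i : i + seg_len]
    if rev:
        seg = seg[::-1]
    rest = np.concatenate((x[:i], x[i + seg_len :]))
    insert_at = p if p <= i else p - seg_len
    return np.concatenate((rest[:insert_at], seg, rest[insert_at:]))


def _local_search(wd: np.ndarray, x: np.ndarray, dummy: int) -> np.ndarray:
    """Alternate best-improvement 2-opt and Or-opt until locally optimal."""
    x = x.copy()
    while True:
        mv = _two_opt_move(wd, x, dummy)
        if mv is not None:
            _, i, j = mv
            x[i : j + 1] = x[i : j + 1][::-1]
            continue
        improved = False
        for seg_len in (1, 2, 3):
            mv = _or_opt_move(wd, x, dummy, seg_len)
            if mv is not None:
                _, i, p, rev = mv
                x = _apply_or_opt(x, i, p, seg_len, rev)
                improved = True
                break
        if not improved:
            return x


def _double_bridge(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(x)
    if n < 4:
        return x.copy()
    cuts = np.sort(rng.choice(np.arange(1, n), size=3, replace=False))
    a, b, c = cuts
    return np.concatenate((x[:a], x[b:c], x[a:b], x[c:]))


def solve_heuristic(
    w: WeightMatrix,
    seed: int = 0,
    restarts: int = 8,
    perturbations: int = 0,
) -> MarkerPath:
    """Heuristic minimum-rf Hamiltonian path through the markers of ``w``.

    Multi-start nearest-neighbour construction + 2-opt/Or-opt descent,
    optionally followed by a chain of double-bridge perturbations with
    re-descent (keeping the best path seen).  Deterministic given
    ``seed``.
    """
    if restarts < 1:
        raise ParameterError("restarts must be >= 1")
    n = w.n_markers
    if n == 1:
        return _path_from_local(w, np.array([0]), "heuristic")
    rng = np.random.default_rng(seed)
    markers = w.weights[:-1, :-1]
    dummy = w.dummy_index
    wd = w.weights

    best: np.ndarray | None = None
    best_cost = None
    starts = [0] + rng.integers(0, n, size=max(restarts - 1, 0)).tolist()
    for start in starts[:restarts]:
        x = _nearest_neighbour(markers, int(start))
        x = _local_search(wd, x, dummy)
        cost = _int_path_cost(markers, x)
        if best_cost is None or cost < best_cost:
            best, best_cost = x, cost
    assert best is not None
    for _ in range(perturbations):
        y = _double_bridge(best, rng)
        y = _local_search(wd, y, dummy)
        cost = _int_path_cost(markers, y)
        if cost < best_cost:
            best, best_cost = y, cost
    return _path_from_local(w, best, "heuristic")


# ---------------------------------------------------------------------------
# exact tier
# ---------------------------------------------------------------------------

def solve_exact_small(w: WeightMatrix, limit: int = DEFAULT_EXACT_LIMIT) -> MarkerPath:
    """Provably optimal Hamiltonian path by Held-Karp subset DP.

    The dummy vertex contributes nothing to any tour cost, so the optimal
    tour through it equals the optimal open path over the markers; the DP
    therefore runs on the marker vertices alone.  Ties are broken toward
    the lexicographically smallest order (which also fixes a canonical
    one of the two reversals).  Raises :class:`SizeError` above ``limit``
    vertices -- larger groups belong to the budgeted heuristic tier (see
    ``ordering.order_linkage_group``).
    """
    if w.size > limit:
        raise SizeError(
            f"{w.size} vertices exceed the exact-solver limit of {limit}; "
            "use ordering.order_linkage_group, which falls back to the "
            "budgeted heuristic"
        )
    n = w.n_markers
    if n == 1:
        return _path_from_local(w, np.array([0]), "exact")
    markers = w.weights[:-1, :-1]
    full = (1 << n) - 1
    f = np.full((1 << n, n), _INF, dtype=np.int64)
    for v in range(n):
        f[1 << v, v] = 0
    wt = markers.T.copy()
    for s in range(3, full + 1):
        vs = [v for v in range(n) if s >> v & 1]
        if len(vs) < 2:
            continue
        prev = np.array([s ^ (1 << v) for v in vs])
        p = f[prev]  # (|vs|, n); entries for u not in prev-set are _INF
        f[s, vs] = (p + wt[vs]).min(axis=1)
    opt = int(f[full].min())
    # lexicographically smallest optimal order, built front to back; by
    # symmetry f[S, v] is also the best cost of a path *starting* at v.
    start = next(v for v in range(n) if f[full, v] == opt)
    order = [start]
    s = full ^ (1 << start)
    cur = start
    target = opt
    while s:
        for u in range(n):
            if s >> u & 1 and markers[cur, u] + f[s, u] == target:
                order.append(u)
                target = int(f[s, u])
                s ^= 1 << u
                cur = u
                break
        else:  # pragma: no cover - DP bookkeeping failure
            raise AssertionError("path reconstruction failed")
    return _path_from_local(w, np.array(order), "exact")


def path_cost(p: MarkerPath, r: RFMatrix) -> float:
    """Sum of rf over adjacent pairs of ``p.order`` (global indices into ``r``)."""
    order = p.order
    if order.min(initial=0) < 0 or order.max(initial=0) >= r.n_markers:
        raise ValidationError("path index out of range for rf matrix")
    if len(order) < 2:
        return 0.0
    return float(r.rf[order[:-1], order[1:]].sum())


# ---------------------------------------------------------------------------
# optional external-solver adapter
# ---------------------------------------------------------------------------

def write_tsplib(w: WeightMatrix, path, name: str = "markers") -> None:
    """Write ``w`` as a TSPLIB EXPLICIT / FULL_MATRIX instance."""
    lines = [
        f"NAME: {name}",
        "TYPE: TSP",
        f"DIMENSION: {w.size}",
        "EDGE_WEIGHT_TYPE: EXPLICIT",
        "EDGE_WEIGHT_FORMAT: FULL_MATRIX",
        "EDGE_WEIGHT_SECTION",
    ]
    for row in w.weights:
        lines.append(" ".join(str(int(v)) for v in row))
    lines.append("EOF")
    Path(path).write_text("\n".join(lines) + "\n")


def solve_external(w: WeightMatrix, executable: str) -> MarkerPath:
    """Order markers with an external TSPLIB tour solver (LKH-style CLI).

    Convenience adapter only: writes the instance and a parameter file,
    runs ``executable``, parses the TOUR_SECTION, and cuts the tour at
    the dummy.  No pipeline stage or test depends on this.
    """
    with tempfile.TemporaryDirectory() as td:
        prob = Path(td) / "instance.tsp"
        tour = Path(td) / "instance.tour"
        par = Path(td) / "instance.par"
        write_tsplib(w, prob)
        par.write_text(
            f"PROBLEM_FILE = {prob}\nOUTPUT_TOUR_FILE = {tour}\nRUNS = 1\n"
        )
        subprocess.run([executable, str(par)], check=True, capture_output=True)
        verts: list[int] = []
        in_section = False
        for line in tour.read_text().splitlines():
            line = line.strip()
            if line == "TOUR_SECTION":
                in_section = True
                continue
            if not in_section:
                continue
            if line in ("-1", "EOF"):
                break
            verts.append(int(line) - 1)
    cut = verts.index(w.dummy_index)
    local = np.array(verts[cut + 1 :] + verts[:cut], dtype=np.int64)
    return _path_from_local(w, local, "external")
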