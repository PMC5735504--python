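"""Final marker ordering and map emission.

Each merged linkage group is ordered by the best available solver: the
Held-Karp exact solver when the group (plus dummy) fits under its vertex
limit, otherwise the heuristic with the high search budget (multi-start
plus a chain of double-bridge perturbations).  The orientation of a
linkage group is biologically arbitrary, so paths are flipped into a
canonical orientation (first marker name lexicographically smallest) and
adjacent rf values are converted to centimorgan positions with a mapping
function (Haldane by default).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .clustering import PipelineParams
from .errors import FormatError, InfiniteDistanceError, ParameterError, ValidationError
from .recombination import RFMatrix
from .tsp import MarkerPath, build_weight_matrix, solve_exact_small, solve_heuristic

MAP_FUNCTIONS = ("haldane", "kosambi", "none")


@dataclass
class LinkageGroup:
    group_id: str
    markers: list[str]  # in map order
    edge_rf: list[float]  # length len(markers) - 1
    positions: list[float]  # cumulative cM, starting at 0
    solver: str = "heuristic"

    def __post_init__(self) -> None:
        if len(self.edge_rf) != max(len(self.markers) - 1, 0):
            raise ValidationError("edge_rf length mismatch")
        if len(self.positions) != len(self.markers):
            raise ValidationError("positions length mismatch")
        if self.positions and self.positions[0] != 0.0:
            raise ValidationError("positions must start at 0")
        if any(b < a - 1e-9 for a, b in zip(self.positions, self.positions[1:])):
            raise ValidationError("positions must be non-decreasing")


@dataclass
class LinkageMap:
    groups: list[LinkageGroup]

    def __post_init__(self) -> None:
        names = [m for g in self.groups for m in g.markers]
        if len(set(names)) != len(names):
            raise ValidationError("a marker appears in more than one group")

    @property
    def n_markers(self) -> int:
        return sum(len(g.markers) for g in self.groups)


def order_linkage_group(
    group: list[int], r: RFMatrix, params: PipelineParams
) -> MarkerPath:
    """Best marker order for one linkage group.

    Groups small enough for Held-Karp get the proven optimum; larger
    groups get the heuristic at the ordering budget
    (``order_restarts`` starts, ``order_perturbations`` double-bridge
    kicks), i.e. the best order found under a fixed, seeded amount of
    search.
    """
    if not group:
        raise ParameterError("group must be non-empty")
    w = build_weight_matrix(r, sorted(group), scale=params.scale)
    if w.size <= params.exact_limit:
        return solve_exact_small(w, limit=params.exact_limit)
    return solve_heuristic(
        w,
        seed=params.seed + 104729 + min(group),
        restarts=params.order_restarts,
        perturbations=params.order_perturbations,
    )


def canonical_orientation(p: MarkerPath, marker_names: list[str]) -> MarkerPath:
    """Flip the path if its last marker name sorts before its first."""
    if len(p.order) >= 2 and marker_names[p.order[-1]] < marker_names[p.order[0]]:
        return p.reversed()
    return p


def map_positions(p: MarkerPath, map_function: str = "haldane") -> np.ndarray:
    """Cumulative cM positions along a path.

    Haldane: d = -50 ln(1 - 2 rf); Kosambi: d = 25 ln((1+2rf)/(1-2rf));
    ``none``: d = 100 rf (a plain rf-sum map).  An adjacent rf of 0.5 is
    an infinite distance under the first two -- the group should be
    re-split instead.
    """
    if map_function not in MAP_FUNCTIONS:
        raise ParameterError(f"unknown map function {map_function!r}")
    rf = np.asarray(p.edge_rf, dtype=np.float64)
    if map_function in ("haldane", "kosambi") and np.any(rf >= 0.5):
        raise InfiniteDistanceError(
            "adjacent rf of 0.5 gives an infinite map distance; re-split the group"
        )
    if map_function == "haldane":
        d = -50.0 * np.log1p(-2.0 * rf)
    elif map_function == "kosambi":
        d = 25.0 * (np.log1p(2.0 * rf) - np.log1p(-2.0 * rf))
    else:
        d = 100.0 * rf
    return np.concatenate(([0.0], np.cumsum(d)))


def write_map(lmap: LinkageMap, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group_id", "order_index", "marker", "rf_to_prev", "position_cM"])
        for g in lmap.groups:
            for i, marker in enumerate(g.markers):
                rf_prev = "" if i == 0 else f"{g.edge_rf[i - 1]:.10g}"
                writer.writerow(
                    [g.group_id, i, marker, rf_prev, f"{g.positions[i]:.10g}"]
                )


def read_map(path) -> LinkageMap:
    """Read a map CSV written by :func:`write_map`; validates monotonicity."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0][:3] != ["group_id", "order_index", "marker"]:
        raise FormatError(f"{path}: missing or malformed header")
    groups: dict[str, dict] = {}
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != 5:
            raise FormatError(f"{path}: line {r} has {len(row)} fields, expected 5")
        gid, idx, marker, rf_prev, pos = row
        g = groups.setdefault(gid, {"markers": [], "edge_rf": [], "positions": []})
        if int(idx) != len(g["markers"]):
            raise FormatError(f"{path}: line {r}: order_index out of sequence")
        g["markers"].append(marker)
        g["positions"].append(float(pos))
        if rf_prev != "":
            g["edge_rf"].append(float(rf_prev))
    return LinkageMap(
        groups=[
            LinkageGroup(group_id=gid, **data) for gid, data in groups.items()
        ]
    )


def write_rotated_map(lmap: LinkageMap, path) -> None:
    """R/qtl-style rotated CSV: markers as columns, group and position rows."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        markers = [m for g in lmap.groups for m in g.markers]
        writer.writerow(markers)
        writer.writerow([g.group_id for g in lmap.groups for _ in g.markers])
        writer.writerow(
            [f"{p:.10g}" for g in lmap.groups for p in g.positions]
        )
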