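"""Solution-quality statistics against a known truth.

Two headline statistics are computed for a map built from simulated
data:

* ``E`` -- erroneous pairs: the number of marker pairs whose relative
  order in the estimated map contradicts their true order, i.e. the
  inversion count between the estimated order and the true ranks.
  Linkage-group orientation is arbitrary, so the count is minimised over
  the two orientations of each group: a perfectly ordered but flipped
  group scores 0.
* ``c`` -- the number of linkage groups produced, to be compared with
  the true chromosome count.

Additionally an absolute Spearman rank correlation between true and
estimated within-group order is reported (orientation-blind by taking
the absolute value), combined across groups weighted by group size, plus
a purity fraction: the share of groups whose markers all come from one
true chromosome.  Markers sitting in a group whose plurality chromosome
is not their own are excluded from that group's E and correlation --
misassignment is reported through purity, keeping E a pure ordering
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .ordering import LinkageMap
from .simulate import TrueMap


@dataclass
class EvalReport:
    E: int
    c: int
    per_group_E: list[int]
    order_correlation: float
    group_purity: float
    n_misassigned: int = 0

    def __post_init__(self) -> None:
        if self.E != sum(self.per_group_E):
            raise ValidationError("E must equal the sum of per-group counts")

    def to_dict(self) -> dict:
        return {
            "E": self.E,
            "c": self.c,
            "per_group_E": list(self.per_group_E),
            "order_correlation": self.order_correlation,
            "group_purity": self.group_purity,
            "n_misassigned": self.n_misassigned,
        }


def _count_inversions(seq: np.ndarray) -> int:
    """Inversions in ``seq`` by merge sort, O(n log n)."""
    seq = list(seq)

    def rec(a: list) -> tuple[list, int]:
        if len(a) <= 1:
            return a, 0
        mid = len(a) // 2
        left, il = rec(a[:mid])
        right, ir = rec(a[mid:])
        merged: list = []
        inv = il + ir
        i = j = 0
        while i < len(left) and j < len(right):
            if left[i] <= right[j]:
                merged.append(left[i])
                i += 1
            else:
                merged.append(right[j])
                j += 1
                inv += len(left) - i
        merged.extend(left[i:])
        merged.extend(right[j:])
        return merged, inv

    return rec(seq)[1]


def erroneous_pairs(true_ranks: dict[str, int], est_order: list[str]) -> int:
    """Discordant marker pairs between an estimated order and true ranks.

    ``true_ranks`` maps marker name to its true rank within the group;
    ranks must be distinct.  The count is minimised over the two
    orientations of ``est_order`` (a reversed group is not an error).
    """
    try:
        ranks = np.array([true_ranks[m] for m in est_order])
    except KeyError as e:
        raise ValidationError(f"marker {e.args[0]!r} absent from truth") from None
    if len(set(ranks.tolist())) != len(ranks):
        raise ValidationError("true ranks must be distinct")
    n = len(ranks)
    inv = _count_inversions(ranks)
    total = n * (n - 1) // 2
    return min(inv, total - inv)


def order_correlation(true_positions: dict[str, float], est_order: list[str]) -> float:
    """Absolute Spearman correlation between estimated and true order.

    Groups of fewer than two markers carry no ordering information and
    return NaN; callers combining across groups should skip them.
    """
    if len(est_order) < 2:
        return float("nan")
    try:
        pos = [true_positions[m] for m in est_order]
    except KeyError as e:
        raise ValidationError(f"marker {e.args[0]!r} absent from truth") from None
    rho = stats.spearmanr(np.arange(len(est_order)), pos).statistic
    return abs(float(rho))


def evaluate_solution(
    lmap: LinkageMap, truth: TrueMap, shuffle: np.ndarray | None = None
) -> EvalReport:
    """Score an estimated map against the simulated truth.

    Each estimated group is assigned to the true chromosome contributing
    the plurality of its markers (ties to the lexicographically smallest
    chromosome name).  E and the correlation are computed over the
    members belonging to that chromosome; markers from other chromosomes
    are counted as misassigned and reflected in ``group_purity``.

    ``shuffle`` is accepted for interface symmetry with the simulator's
    marker randomisation but is not needed: markers are matched by name.
    """
    chrom_of = truth.marker_chromosome()
    pos_of = truth.marker_position()
    # true within-chromosome rank of every marker
    rank_of: dict[str, int] = {}
    for c in truth.chromosomes:
        order = np.argsort(c.positions_cm, kind="stable")
        for rank, idx in enumerate(order):
            rank_of[c.marker_names[idx]] = rank

    per_group_E: list[int] = []
    weights: list[int] = []
    rhos: list[float] = []
    pure_groups = 0
    misassigned = 0
    for g in lmap.groups:
        chroms = [chrom_of.get(m) for m in g.markers]
        if any(c is None for c in chroms):
            missing = g.markers[chroms.index(None)]
            raise ValidationError(f"marker {missing!r} absent from truth")
        counts: dict[str, int] = {}
        for c in chroms:
            counts[c] = counts.get(c, 0) + 1
        plurality = min(counts, key=lambda c: (-counts[c], c))
        if len(counts) == 1:
            pure_groups += 1
        own = [m for m, c in zip(g.markers, chroms) if c == plurality]
        misassigned += len(g.markers) - len(own)
        ranks = {m: rank_of[m] for m in own}
        per_group_E.append(erroneous_pairs(ranks, own))
        if len(own) >= 2:
            rhos.append(order_correlation(pos_of, own))
            weights.append(len(own))

    corr = (
        float(np.average(rhos, weights=weights)) if weights else float("nan")
    )
    purity = pure_groups / len(lmap.groups) if lmap.groups else float("nan")
    return EvalReport(
        E=int(sum(per_group_E)),
        c=len(lmap.groups),
        per_group_E=per_group_E,
        order_correlation=corr,
        group_purity=purity,
        n_misassigned=misassigned,
    )
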