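"""Three-stage merging of over-cut clusters into final linkage groups.

Clusters are processed smallest-first (a small fragment is the likeliest
candidate for absorption into a larger group).  For the cluster under
consideration, three increasingly expensive tests are tried:

1. *direct* -- matrix evidence only: if the minimum inter-cluster rf to
   the best candidate is small (<= ``direct_threshold``) and clearly
   unique (at most half the second-best link), merge without solving
   anything.
2. *path* -- combine the cluster pairwise with each nearby candidate and
   solve the joint Hamiltonian path; the merge statistic J is the
   maximum adjacent rf anywhere in the joint path.  Merge when the best
   J is less than half the next smallest J.
3. *reciprocal* -- if the best candidate by J, examined from its own
   side, also picks this cluster as its best partner, merge.

A cluster failing all three is a complete linkage group.  Every accepted
merge must additionally survive the re-split guard: no *boundary* edge
of the joint path (an adjacency connecting a marker of one cluster to a
marker of the other) may exceed ``break_threshold``, otherwise the
splitting criterion would immediately separate the two clusters again.
Jumps internal to one cluster do not veto a merge -- they belong to that
cluster regardless of the decision, and at high noise the budgeted
solver can show spurious internal jumps.  Since any joint path must
cross between the two clusters at least once, the boundary maximum is
bounded below by the minimum inter-cluster rf -- so candidates whose
best link already exceeds ``break_threshold`` are skipped without
solving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import ClusterSet, PipelineParams
from .errors import ValidationError
from .recombination import RFMatrix
from .tsp import build_weight_matrix, solve_heuristic

MERGE_STAGES = ("direct", "path", "reciprocal", "standalone")


@dataclass
class MergeDecision:
    source_cluster: int
    target_cluster: int | None
    stage: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in MERGE_STAGES:
            raise ValidationError(f"unknown merge stage {self.stage!r}")
        if (self.stage == "standalone") != (self.target_cluster is None):
            raise ValidationError("standalone decisions must have no target")


def _min_link(r: RFMatrix, x: list[int], y: list[int]) -> float:
    return float(r.rf[np.ix_(x, y)].min())


class _Merger:
    def __init__(self, cs: ClusterSet, r: RFMatrix, params: PipelineParams) -> None:
        self.r = r
        self.params = params
        self.clusters: dict[int, list[int]] = {
            i: list(cl) for i, cl in enumerate(cs.clusters)
        }
        self.next_id = len(self.clusters)
        self.standalone: set[int] = set()
        self.decisions: list[MergeDecision] = []
        self._j_cache: dict[tuple[int, int], tuple[float, list[int]]] = {}
        self._solver_calls = 0

    # -- statistics ------------------------------------------------------
    def links_from(self, cid: int) -> list[tuple[float, int]]:
        """Sorted (min inter-cluster rf, candidate id) list for cluster cid."""
        x = self.clusters[cid]
        out = [
            (_min_link(self.r, x, y), oid)
            for oid, y in self.clusters.items()
            if oid != cid
        ]
        return sorted(out)

    def joint_path(self, a: int, b: int) -> tuple[float, float]:
        """J statistics of the joint path of clusters a and b.

        Returns (max adjacent rf anywhere, max adjacent rf over boundary
        edges connecting the two clusters).
        """
        key = (min(a, b), max(a, b))
        if key not in self._j_cache:
            union = sorted(self.clusters[a] + self.clusters[b])
            w = build_weight_matrix(self.r, union, scale=self.params.scale)
            self._solver_calls += 1
            path = solve_heuristic(
                w,
                seed=self.params.seed + 7919 * (key[0] + 1) + key[1],
                restarts=self.params.cluster_restarts,
            )
            j = float(path.edge_rf.max()) if len(path.edge_rf) else 0.0
            in_a = set(self.clusters[min(a, b)])
            order = path.order
            boundary = [
                float(rf)
                for u, v, rf in zip(order[:-1], order[1:], path.edge_rf)
                if (int(u) in in_a) != (int(v) in in_a)
            ]
            j_boundary = max(boundary) if boundary else 0.0
            self._j_cache[key] = (j, j_boundary)
        return self._j_cache[key]

    def path_candidates(self, cid: int) -> list[int]:
        """Candidates worth solving: nearby by link and potentially guard-safe."""
        links = self.links_from(cid)
        cands = [
            oid
            for link, oid in links
            if link <= self.params.break_threshold
        ]
        return cands[: self.params.merge_candidates]

    def best_by_j(self, cid: int) -> list[tuple[float, int]]:
        return sorted(
            (self.joint_path(cid, oid)[0], oid) for oid in self.path_candidates(cid)
        )

    # -- stages ----------------------------------------------------------
    def try_direct(self, cid: int) -> tuple[int, dict] | None:
        links = self.links_from(cid)
        if not links:
            return None
        best_link, best_id = links[0]
        second = links[1][0] if len(links) > 1 else np.inf
        if best_link <= self.params.direct_threshold and (
            best_link <= self.params.stage_ratio * second
        ):
            return best_id, {
                "link": best_link,
                "second_link": None if np.isinf(second) else second,
            }
        return None

    def try_path(self, cid: int) -> tuple[int, dict] | None:
        js = self.best_by_j(cid)
        if not js:
            return None
        best_j, best_id = js[0]
        second = js[1][0] if len(js) > 1 else np.inf
        if best_j < self.params.stage_ratio * second:
            return best_id, {
                "J": best_j,
                "second_J": None if np.isinf(second) else second,
            }
        return None

    def try_reciprocal(self, cid: int) -> tuple[int, dict] | None:
        js = self.best_by_j(cid)
        if not js:
            return None
        best_j, best_id = js[0]
        if best_j > self.params.cutoff:
            return None
        back = self.best_by_j(best_id)
        if back and back[0][1] == cid:
            return best_id, {"J": best_j, "reciprocal_J": back[0][0]}
        return None

    def guard_ok(self, a: int, b: int) -> bool:
        """Re-split guard: no boundary edge of the joint path may exceed
        break_threshold (the split stage would undo such a merge)."""
        _, j_boundary = self.joint_path(a, b)
        return j_boundary <= self.params.break_threshold

    # -- main loop -------------------------------------------------------
    def merge(self, src: int, dst: int, stage: str, evidence: dict) -> None:
        self.decisions.append(MergeDecision(src, dst, stage, evidence))
        merged = sorted(self.clusters[src] + self.clusters[dst])
        del self.clusters[src], self.clusters[dst]
        self.standalone.discard(src)
        self.standalone.discard(dst)
        self._j_cache = {
            k: v for k, v in self._j_cache.items() if src not in k and dst not in k
        }
        self.clusters[self.next_id] = merged
        self.next_id += 1

    def run(self) -> tuple[ClusterSet, list[MergeDecision]]:
        while True:
            pending = [
                cid for cid in self.clusters if cid not in self.standalone
            ]
            if not pending:
                break
            # smallest first, ties by id
            cid = min(pending, key=lambda c: (len(self.clusters[c]), c))
            merged = False
            for stage, attempt in (
                ("direct", self.try_direct),
                ("path", self.try_path),
                ("reciprocal", self.try_reciprocal),
            ):
                found = attempt(cid)
                if found is None:
                    continue
                target, evidence = found
                if not self.guard_ok(cid, target):
                    evidence = dict(evidence, guard_rejected=True)
                    continue
                self.merge(cid, target, stage, evidence)
                merged = True
                break
            if not merged:
                self.standalone.add(cid)
                self.decisions.append(MergeDecision(cid, None, "standalone"))
        clusters = [
            self.clusters[cid]
            for cid in sorted(self.clusters, key=lambda c: self.clusters[c][0])
        ]
        return ClusterSet(clusters=clusters, stage="merged"), self.decisions


def merge_clusters(
    cs: ClusterSet, r: RFMatrix, params: PipelineParams
) -> tuple[ClusterSet, list[MergeDecision]]:
    """Run the three-stage merge; see module docstring for the procedure."""
    if cs.stage != "split":
        raise ValidationError("merge_clusters expects a ClusterSet at stage 'split'")
    return _Merger(cs, r, params).run()


def count_groups(cs: ClusterSet) -> int:
    """The c statistic: number of linkage groups in a merged solution."""
    return len(cs.clusters)


def decisions_to_frame(decisions: list[MergeDecision]):
    """Merge-decision audit log as a tidy table."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "source_cluster": d.source_cluster,
                "target_cluster": d.target_cluster,
                "stage": d.stage,
                **{f"evidence_{k}": v for k, v in d.evidence.items()},
            }
            for d in decisions
        ]
    )
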