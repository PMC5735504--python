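"""End-to-end map construction: filter -> rf -> cutoff -> cluster -> split
-> merge -> order.

This is the library-level entry point the CLI wraps.  It accepts either
a genotype matrix (rf is then estimated per the cross design) or a
precomputed rf matrix (for designs estimated elsewhere, e.g. 4-way
crosses from R/qtl), and returns the final :class:`LinkageMap` together
with every intermediate artifact for auditing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .clustering import ClusterSet, PipelineParams, initial_clusters, split_clusters
from .errors import ParameterError, ValidationError
from .genotypes import FilterReport, GenotypeMatrix, filter_markers
from .merging import MergeDecision, count_groups, merge_clusters
from .ordering import (
    LinkageGroup,
    LinkageMap,
    canonical_orientation,
    map_positions,
    order_linkage_group,
)
from .recombination import RFMatrix, apply_cutoff, rf_backcross, rf_f2_em, rf_homozygous


@dataclass
class PipelineResult:
    linkage_map: LinkageMap
    rf: RFMatrix
    filter_report: FilterReport | None
    clusters_initial: ClusterSet
    clusters_split: ClusterSet
    clusters_merged: ClusterSet
    merge_decisions: list[MergeDecision]

    @property
    def n_groups(self) -> int:
        return count_groups(self.clusters_merged)


def estimate_rf(g: GenotypeMatrix) -> RFMatrix:
    """Dispatch rf estimation on the cross design."""
    if g.cross_type in ("riself", "unknown"):
        return rf_homozygous(g)
    if g.cross_type == "bc":
        return rf_backcross(g)
    if g.cross_type == "f2":
        return rf_f2_em(g)
    raise ValidationError(f"no rf estimator for cross type {g.cross_type!r}")


def cluster_markers(
    r: RFMatrix, params: PipelineParams
) -> tuple[ClusterSet, ClusterSet, ClusterSet, list[MergeDecision]]:
    """Clustering phase only: cutoff-inflated rf in, merged linkage groups out."""
    cs0 = initial_clusters(r, params)
    cs1 = split_clusters(cs0, r, params)
    cs2, decisions = merge_clusters(cs1, r, params)
    return cs0, cs1, cs2, decisions


def construct_map(
    params: PipelineParams,
    genotypes: GenotypeMatrix | None = None,
    rf: RFMatrix | None = None,
    similarity_threshold: float = 1.0,
    max_het_fraction: float = 0.10,
) -> PipelineResult:
    """Run the full pipeline from genotypes or a precomputed rf matrix."""
    if (genotypes is None) == (rf is None):
        raise ParameterError("provide exactly one of genotypes or rf")

    filter_report = None
    if genotypes is not None:
        genotypes, filter_report = filter_markers(
            genotypes, similarity_threshold, max_het_fraction
        )
        rf = estimate_rf(genotypes)
    assert rf is not None
    rf = apply_cutoff(rf, params.cutoff)

    cs0, cs1, cs2, decisions = cluster_markers(rf, params)

    # order groups largest-first for stable LG numbering
    group_order = sorted(
        range(len(cs2.clusters)),
        key=lambda i: (-len(cs2.clusters[i]), cs2.clusters[i][0]),
    )
    groups: list[LinkageGroup] = []
    for rank, gi in enumerate(group_order, start=1):
        members = cs2.clusters[gi]
        path = order_linkage_group(members, rf, params)
        path = canonical_orientation(path, rf.marker_names)
        positions = map_positions(path, params.map_function)
        groups.append(
            LinkageGroup(
                group_id=f"LG{rank}",
                markers=[rf.marker_names[i] for i in path.order],
                edge_rf=[float(v) for v in path.edge_rf],
                positions=[float(v) for v in positions],
                solver=path.solver,
            )
        )
    return PipelineResult(
        linkage_map=LinkageMap(groups),
        rf=rf,
        filter_report=filter_report,
        clusters_initial=cs0,
        clusters_split=cs1,
        clusters_merged=cs2,
        merge_decisions=decisions,
    )
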