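"""Regrouping of histology-specific TNM subgroups by survival-curve distance.

One Kaplan-Meier curve is fitted per coarse histology x T x N x M subgroup;
pairwise per-capita log-rank chi-square values form a distance matrix;
agglomerative clustering over that matrix is cut into eight clusters which
are ordered by pooled 5-year cancer-specific survival and relabelled
IA..IV (nesting 2+2+3+1 into stages I..IV).  The result is a data-driven
stage map directly comparable to the 8th-edition and published-modified maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .staging_maps import (
    StageLabel,
    StageMap,
    SubgroupKey,
    SUBSTAGES,
    STAGE_PATTERN,
    assign_substage_8th_coarse,
    coarsen,
)
from .survival_core import (
    CohortRecord,
    SurvivalCurve,
    css_at,
    curve_chi2_distance,
    km_estimate,
    regrid,
)

FIVE_YEARS = 60.0  # months


@dataclass
class SubgroupCurveSet:
    """KM curve and patient count per subgroup, all curves on one shared grid."""

    entries: Dict[SubgroupKey, Tuple[SurvivalCurve, int]]
    excluded: Dict[SubgroupKey, int] = field(default_factory=dict)

    @property
    def grid(self) -> np.ndarray:
        first = next(iter(self.entries.values()))
        return first[0].grid


@dataclass
class DistanceMatrix:
    labels: List[SubgroupKey]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0) or np.any(self.d < 0):
            raise ValueError("distances must be non-negative with zero diagonal")

    def to_tsv(self) -> str:
        header = "subgroup\t" + "\t".join(k.label for k in self.labels)
        lines = [header]
        for k, row in zip(self.labels, self.d):
            lines.append(k.label + "\t" + "\t".join(f"{x:.10g}" for x in row))
        return "\n".join(lines) + "\n"


@dataclass
class ClusterTree:
    """Agglomerative merge tree (scipy linkage matrix) over subgroup labels."""

    labels: List[SubgroupKey]
    linkage_matrix: np.ndarray
    method: str


@dataclass
class Regrouping:
    """Cut clusters ordered by pooled 5-year CSS and labelled IA..IV."""

    k: int
    assignment: Dict[SubgroupKey, int]
    cluster_labels: Dict[int, StageLabel]
    cluster_css5: Dict[int, float]

    def stage_of(self, key: SubgroupKey) -> StageLabel:
        return self.cluster_labels[self.assignment[key]]

    def to_json_dict(self) -> dict:
        return {
            "k": self.k,
            "clusters": [
                {
                    "substage": self.cluster_labels[c].substage,
                    "stage": self.cluster_labels[c].stage,
                    "css_5yr": self.cluster_css5[c],
                    "subgroups": sorted(k.label for k, cid in self.assignment.items()
                                        if cid == c),
                }
                for c in sorted(self.cluster_labels,
                                key=lambda c: self.cluster_labels[c].substage_rank)
            ],
        }


def build_curve_set(records: Sequence[CohortRecord],
                    min_group_size: int = 30,
                    grid_step: float = 1.0) -> SubgroupCurveSet:
    """One KM curve per subgroup present in the data, on a common monthly grid.

    Subgroups with fewer than ``min_group_size`` patients are excluded from
    clustering and reported in ``excluded`` (they are later assigned through
    their 8th-edition cell in the derived map).
    """
    if len(records) == 0:
        raise ValueError("cannot build a curve set from an empty cohort")
    by_key: Dict[SubgroupKey, List[CohortRecord]] = {}
    for r in records:
        by_key.setdefault(coarsen(r.category), []).append(r)

    included = {k: v for k, v in by_key.items() if len(v) >= min_group_size}
    excluded = {k: len(v) for k, v in by_key.items() if len(v) < min_group_size}
    if not included:
        raise ValueError(
            f"all {len(by_key)} subgroups fall below min_group_size={min_group_size}"
        )

    t_max = max(r.time for k in included for r in by_key[k])
    n_points = max(1, int(np.ceil(t_max / grid_step - 1e-9)))
    common_grid = grid_step * np.arange(1, n_points + 1)

    entries: Dict[SubgroupKey, Tuple[SurvivalCurve, int]] = {}
    for k in sorted(included, key=lambda key: key.label):
        curve = km_estimate(by_key[k], grid_step=grid_step)
        entries[k] = (regrid(curve, common_grid), len(by_key[k]))
    return SubgroupCurveSet(entries=entries, excluded=excluded)


def build_distance_matrix(curve_set: SubgroupCurveSet) -> DistanceMatrix:
    """Pairwise per-capita log-rank chi-square distances between subgroup curves."""
    labels = list(curve_set.entries)
    if len(labels) < 2:
        raise ValueError("need at least two subgroups to build a distance matrix")
    n = len(labels)
    d = np.zeros((n, n))
    curves = [curve_set.entries[k][0] for k in labels]
    for i in range(n):
        for j in range(i + 1, n):
            chi2 = curve_chi2_distance(curves[i], curves[j], "infinite").chi2
            d[i, j] = d[j, i] = chi2
    return DistanceMatrix(labels=labels, d=d)


def agglomerate(m: DistanceMatrix, linkage: str = "average") -> ClusterTree:
    """Agglomerative clustering of the precomputed distance matrix."""
    if linkage not in ("average", "complete", "single"):
        raise ValueError("linkage must be one of: average, complete, single")
    condensed = squareform(m.d, checks=False)
    z = hierarchy.linkage(condensed, method=linkage)
    return ClusterTree(labels=list(m.labels), linkage_matrix=z, method=linkage)


def _pooled_css(members: Sequence[SubgroupKey],
                curve_set: SubgroupCurveSet, horizon: float) -> float:
    # n-weighted mean of subgroup survival: the curve-only stand-in for a
    # pooled KM refit (exact when subgroups are uncensored).
    weights = np.array([curve_set.entries[k][1] for k in members], dtype=float)
    values = np.array([css_at(curve_set.entries[k][0], horizon) for k in members])
    return float(np.average(values, weights=weights))


def _pooled_median(members: Sequence[SubgroupKey],
                   curve_set: SubgroupCurveSet) -> float:
    grid = curve_set.grid
    weights = np.array([curve_set.entries[k][1] for k in members], dtype=float)
    stacked = np.vstack([curve_set.entries[k][0].s for k in members])
    pooled = np.average(stacked, axis=0, weights=weights)
    below = np.nonzero(pooled <= 0.5)[0]
    return float(grid[below[0]]) if len(below) else float("inf")


def cut_and_label(tree: ClusterTree, curve_set: SubgroupCurveSet,
                  k_substage: int = 8,
                  stage_pattern: Tuple[int, ...] = STAGE_PATTERN) -> Regrouping:
    """Cut the merge tree into sub-stage clusters ordered by 5-year CSS.

    Clusters are sorted by decreasing pooled 5-year CSS (ties: larger pooled
    median survival first, then larger cluster first) and labelled IA..IV;
    consecutive sub-stages nest into stages by ``stage_pattern``.
    """
    if sum(stage_pattern) != k_substage:
        raise ValueError(
            f"stage_pattern {stage_pattern} must sum to k_substage={k_substage}"
        )
    n_leaves = len(tree.labels)
    if k_substage > n_leaves:
        raise ValueError(
            f"cannot cut {n_leaves} subgroups into {k_substage} clusters"
        )
    flat = hierarchy.cut_tree(tree.linkage_matrix, n_clusters=k_substage).ravel()
    members: Dict[int, List[SubgroupKey]] = {}
    for key, cid in zip(tree.labels, flat):
        members.setdefault(int(cid), []).append(key)

    substage_names = _substage_names(k_substage, stage_pattern)
    order = sorted(
        members,
        key=lambda c: (-_pooled_css(members[c], curve_set, FIVE_YEARS),
                       -_pooled_median(members[c], curve_set),
                       -sum(curve_set.entries[k][1] for k in members[c])),
    )
    cluster_labels: Dict[int, StageLabel] = {}
    cluster_css5: Dict[int, float] = {}
    for rank, cid in enumerate(order):
        cluster_labels[cid] = StageLabel.from_substage(substage_names[rank])
        cluster_css5[cid] = _pooled_css(members[cid], curve_set, FIVE_YEARS)
    assignment = {key: int(cid) for key, cid in zip(tree.labels, flat)}
    return Regrouping(k=k_substage, assignment=assignment,
                      cluster_labels=cluster_labels, cluster_css5=cluster_css5)


def _substage_names(k: int, pattern: Tuple[int, ...]) -> List[str]:
    if k == 8 and tuple(pattern) == STAGE_PATTERN:
        return list(SUBSTAGES)
    raise ValueError(
        "only the 8-sub-stage (2, 2, 3, 1) labelling is defined; "
        f"got k={k}, pattern={tuple(pattern)}"
    )


def derive_stage_map(r: Regrouping,
                     excluded: Optional[Dict[SubgroupKey, int]] = None) -> StageMap:
    """Stage map produced by the clustering (source ``"derived"``).

    Subgroups excluded from clustering (too few patients) fall back to their
    8th-edition coarse assignment with source ``"default"``.
    """
    entries: Dict[SubgroupKey, StageLabel] = {}
    sources: Dict[SubgroupKey, str] = {}
    for key in r.assignment:
        entries[key] = r.stage_of(key)
        sources[key] = "derived"
    for key in (excluded or {}):
        if key not in entries:
            entries[key] = assign_substage_8th_coarse(key)
            sources[key] = "default"
    return StageMap("derived_modified", entries, sources)


def export_newick(tree: ClusterTree) -> str:
    """Newick serialization of the merge tree with ultrametric branch lengths.

    A node merged at height h sits at depth h/2, so two leaves joined at
    height 1.0 render as ``(A:0.5,B:0.5);``.
    """
    z = tree.linkage_matrix
    n = len(tree.labels)

    def height(node: int) -> float:
        return 0.0 if node < n else float(z[node - n, 2])

    def render(node: int, parent_h: float) -> str:
        length = (parent_h - height(node)) / 2.0
        if node < n:
            return f"{tree.labels[node].label}:{length:.10g}"
        left, right = int(z[node - n, 0]), int(z[node - n, 1])
        h = height(node)
        return f"({render(left, h)},{render(right, h)}):{length:.10g}"

    if n == 1:
        return f"{tree.labels[0].label}:0;"
    root = n + len(z) - 1
    h_root = height(root)
    left, right = int(z[-1, 0]), int(z[-1, 1])
    return f"({render(left, h_root)},{render(right, h_root)});"
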