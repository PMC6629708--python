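"""Neighbor-joining trees, column bootstrap, monophyly, and the
subfamily-rank decision rule.

Trees are built by neighbor joining on uncorrected p-distances of a
concatenated partition and rooted by a named outgroup.  Clade support is the
percentage of column-resampled bootstrap replicates whose NJ tree contains
the clade.  The rank rule mirrors how deep taxonomic rank is argued when the
focal lineage's exact placement is unresolved: what must be strongly
supported is (i) a clade the focal lineage is *inside* (so it belongs to the
group at all) and (ii) a clade of equal rank it is *outside* (so it is not
subordinate to any existing subfamily) — the bootstrap value of the focal
lineage's own attachment point is irrelevant to the decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .distbar import p_distance

RECOMMEND_SUBFAMILY = "subfamily"
RECOMMEND_INSUFFICIENT = "insufficient_support"

SCENARIOS = ("sister_to_pair_1", "sister_to_pair_2", "sisters_with_other")


class TreeError(ValueError):
    pass


def pdistance_matrix(matrix: np.ndarray, ids: Sequence[str]) -> DistanceMatrix:
    """Pairwise uncorrected p-distances between alignment rows."""
    n = len(ids)
    if matrix.shape[0] != n:
        raise TreeError("row count does not match taxon ids")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = p_distance(matrix[i], matrix[j]).p_distance
            out[i, j] = out[j, i] = d
    return DistanceMatrix(out, ids=list(ids))


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (unrooted, trifurcating root node).

    On an additive matrix the tree's path distances reproduce the input
    exactly.  Negative branch-length estimates are clamped to zero.
    """
    if dm.shape[0] < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")
    arr = np.asarray(dm.data)
    if not np.allclose(arr, arr.T) or not np.allclose(np.diag(arr), 0):
        raise TreeError("distance matrix must be symmetric with zero diagonal")
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def root_with_outgroup(tree: TreeNode, outgroup: str | Iterable[str]) -> TreeNode:
    names = [outgroup] if isinstance(outgroup, str) else list(outgroup)
    return tree.root_by_outgroup(names)


def clades_of(tree: TreeNode) -> set[frozenset[str]]:
    """Tip-name sets of all internal nodes of a rooted tree (root excluded)."""
    out = set()
    for node in tree.non_tips(include_self=False):
        out.add(frozenset(t.name for t in node.tips()))
    return out


def is_monophyletic(tree: TreeNode, taxa: Iterable[str]) -> bool:
    """True iff *taxa* form an exact clade of the rooted tree."""
    taxa = frozenset(taxa)
    tips = {t.name for t in tree.tips()}
    unknown = taxa - tips
    if unknown:
        raise TreeError(f"unknown taxa: {sorted(unknown)}")
    if len(taxa) <= 1 or taxa == tips:
        return True
    lca = tree.lca(sorted(taxa))
    return {t.name for t in lca.tips()} == set(taxa)


def bootstrap_support(
    matrix: np.ndarray,
    ids: Sequence[str],
    n_replicates: int,
    seed: int,
    outgroup: str | None = None,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree with bootstrap supports from column resampling.

    Each replicate resamples alignment columns with replacement, rebuilds the
    NJ tree, and (when an outgroup is given) roots it identically to the
    full-data tree.  Support of a clade is the percentage of replicate trees
    containing it.  Fully deterministic for a given seed.
    """
    if n_replicates < 1:
        raise TreeError("need at least one bootstrap replicate")
    base = nj_tree(pdistance_matrix(matrix, ids))
    if outgroup is not None:
        base = root_with_outgroup(base, outgroup)
    target_clades = clades_of(base)
    counts = {c: 0 for c in target_clades}
    rng = np.random.default_rng(seed)
    n_cols = matrix.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = nj_tree(pdistance_matrix(matrix[:, cols], ids))
        if outgroup is not None:
            rep = root_with_outgroup(rep, outgroup)
        rep_clades = clades_of(rep)
        for c in target_clades:
            if c in rep_clades:
                counts[c] += 1
    supports = {c: 100.0 * counts[c] / n_replicates for c in target_clades}
    for node in base.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        node.name = f"{supports[clade]:g}"
    return base, supports


def clade_support(
    supports: Mapping[frozenset[str], float], taxa: Iterable[str]
) -> float:
    """Support of an exact clade; 0 if the tree does not contain it.

    A single taxon is trivially a clade, so singletons get 100."""
    taxa = frozenset(taxa)
    if len(taxa) == 1:
        return 100.0
    return supports.get(taxa, 0.0)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


@dataclass(frozen=True)
class TreeEvidence:
    """What one tree says about one reference clade."""

    support: float
    contains_focal: bool

    def __post_init__(self) -> None:
        if not 0 <= self.support <= 100:
            raise ValueError("support must be a percentage in [0, 100]")


@dataclass(frozen=True)
class CladeSupportReport:
    """Per-tree evidence for the rank decision.

    ``inclusion`` is the clade the focal lineage must belong to (focal plus
    all candidate sisters); ``exclusion`` is the well-supported clade of
    equal rank the focal lineage must fall outside of.  ``focal_placement``
    records the bootstrap value at the focal lineage's attachment node in
    each tree — reported for transparency, never consulted by the rule.
    """

    focal_clade: frozenset[str]
    inclusion: Mapping[str, TreeEvidence]
    exclusion: Mapping[str, TreeEvidence]
    focal_placement: Mapping[str, float] = field(default_factory=dict)
    scenario: str = "unresolved"

    def __post_init__(self) -> None:
        if not self.inclusion or not self.exclusion:
            raise ValueError("report needs inclusion and exclusion clade evidence")
        if set(self.inclusion) != set(self.exclusion):
            raise ValueError("inclusion and exclusion must cover the same trees")


@dataclass(frozen=True)
class RankDecision:
    scenario: str
    recommendation: str
    rationale: tuple[str, ...]


def rank_decision(report: CladeSupportReport, strong_threshold: float = 95.0) -> RankDecision:
    """Subfamily iff, in every tree, the inclusion clade is strongly supported
    and contains the focal lineage, and the exclusion clade is strongly
    supported and does not — regardless of where inside the inclusion clade
    the focal lineage attaches."""
    rationale: list[str] = []
    ok = True
    for tree_name in sorted(report.inclusion):
        ev = report.inclusion[tree_name]
        if ev.support < strong_threshold:
            ok = False
            rationale.append(
                f"{tree_name}: inclusion clade support {ev.support:g}% < {strong_threshold:g}%"
            )
        elif not ev.contains_focal:
            ok = False
            rationale.append(f"{tree_name}: focal clade outside the inclusion clade")
        else:
            rationale.append(
                f"{tree_name}: inclusion clade holds ({ev.support:g}%, focal inside)"
            )
    for tree_name in sorted(report.exclusion):
        ev = report.exclusion[tree_name]
        if ev.support < strong_threshold:
            ok = False
            rationale.append(
                f"{tree_name}: exclusion clade support {ev.support:g}% < {strong_threshold:g}%"
            )
        elif ev.contains_focal:
            ok = False
            rationale.append(f"{tree_name}: focal clade inside the exclusion clade")
        else:
            rationale.append(
                f"{tree_name}: exclusion clade holds ({ev.support:g}%, focal outside)"
            )
    if ok:
        rationale.append("placement of the focal clade within the inclusion clade "
                         "is irrelevant to the recommendation")
    return RankDecision(
        scenario=report.scenario,
        recommendation=RECOMMEND_SUBFAMILY if ok else RECOMMEND_INSUFFICIENT,
        rationale=tuple(rationale),
    )


def classify_scenario(
    tree: TreeNode,
    focal: frozenset[str],
    other: frozenset[str],
    third: frozenset[str],
) -> str:
    """Which of the three placements of focal / other / third holds in a
    rooted tree: focal sister to (other+third), other sister to (focal+third),
    or focal and other sisters."""
    if is_monophyletic(tree, other | third):
        return "sister_to_pair_1"
    if is_monophyletic(tree, focal | third):
        return "sister_to_pair_2"
    if is_monophyletic(tree, focal | other):
        return "sisters_with_other"
    return "unresolved"


def build_support_report(
    trees_and_supports: Mapping[str, tuple[TreeNode, Mapping[frozenset[str], float]]],
    focal: Iterable[str],
    inclusion: Iterable[str],
    exclusion: Iterable[str],
    scenario_other: Iterable[str] | None = None,
    scenario_third: Iterable[str] | None = None,
) -> CladeSupportReport:
    """Assemble a CladeSupportReport from bootstrapped trees.

    ``inclusion``/``exclusion`` are taxon sets; per tree we record their
    bootstrap support and whether the focal clade sits inside them.  The
    focal attachment support is the bootstrap value of the focal clade's
    parent node when the focal clade exists in that tree.
    """
    focal = frozenset(focal)
    inclusion = frozenset(inclusion)
    exclusion = frozenset(exclusion)
    inc, exc, placement = {}, {}, {}
    scenario = "unresolved"
    for name, (tree, supports) in trees_and_supports.items():
        inc[name] = TreeEvidence(
            support=clade_support(supports, inclusion),
            contains_focal=focal <= inclusion,
        )
        exc[name] = TreeEvidence(
            support=clade_support(supports, exclusion),
            contains_focal=focal <= exclusion,
        )
        placement[name] = clade_support(supports, focal) if len(focal) > 1 else (
            supports.get(_parent_clade(tree, focal), 0.0)
        )
        if scenario_other is not None and scenario_third is not None:
            sc = classify_scenario(
                tree, focal, frozenset(scenario_other), frozenset(scenario_third)
            )
            if sc != "unresolved":
                scenario = sc
    return CladeSupportReport(
        focal_clade=focal,
        inclusion=inc,
        exclusion=exc,
        focal_placement=placement,
        scenario=scenario,
    )


def report_to_dict(report: CladeSupportReport) -> dict:
    return {
        "focal_clade": sorted(report.focal_clade),
        "scenario": report.scenario,
        "trees": {
            name: {
                "inclusion": {
                    "support": report.inclusion[name].support,
                    "contains_focal": report.inclusion[name].contains_focal,
                },
                "exclusion": {
                    "support": report.exclusion[name].support,
                    "contains_focal": report.exclusion[name].contains_focal,
                },
                "focal_placement": report.focal_placement.get(name),
            }
            for name in sorted(report.inclusion)
        },
    }


def report_from_dict(data: Mapping) -> CladeSupportReport:
    trees = data["trees"]
    return CladeSupportReport(
        focal_clade=frozenset(data["focal_clade"]),
        inclusion={
            name: TreeEvidence(
                support=ev["inclusion"]["support"],
                contains_focal=bool(ev["inclusion"]["contains_focal"]),
            )
            for name, ev in trees.items()
        },
        exclusion={
            name: TreeEvidence(
                support=ev["exclusion"]["support"],
                contains_focal=bool(ev["exclusion"]["contains_focal"]),
            )
            for name, ev in trees.items()
        },
        focal_placement={
            name: ev["focal_placement"]
            for name, ev in trees.items()
            if ev.get("focal_placement") is not None
        },
        scenario=data.get("scenario", "unresolved"),
    )


def _parent_clade(tree: TreeNode, focal: frozenset[str]) -> frozenset[str]:
    node = tree.lca(sorted(focal)) if len(focal) > 1 else tree.find(next(iter(focal)))
    parent = node.parent if node.parent is not None else node
    return frozenset(t.name for t in parent.tips())
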