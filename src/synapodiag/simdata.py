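"""Synthetic partitioned alignments with known planted synapomorphies.

The generator stands in for a real multi-genome dataset: exon loci evolved
along a known rooted tree (Yule birth process or a user-supplied newick)
under JC69 or GTR, a focal clade constrained to be monophyletic so ground
truth exists, a chosen number of clade-invariant diagnostic substitutions
planted at known positions, and per-cell missing-data masks and
negative-binomial read-depth values emulating uneven sequencing coverage.

Defaults emulate a desk-scale study: 12 taxa, 20 exon loci of 300 bp across
nuclear/Z/mito partitions plus one 658-bp COI barcode locus, a 4-taxon focal
clade with 10 planted synapomorphies, 5% missing cells, and mean read depth
25 (moderate-coverage shotgun data).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.linalg import expm
from skbio import TreeNode

from .alignio import (
    COI_BARCODE_LENGTH,
    AlignmentSet,
    CladePartition,
    LocusRef,
    concatenate,
    write_alignments,
    write_clades,
)
from .notation import KIND_DERIVED, DiagnosticCharacter, render
from .treesupport import is_monophyletic, write_newick

BASES = np.array(["A", "C", "G", "T"])
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# rng stream offsets so evolution / planting / masking never share a stream
_PLANT_OFFSET = 500_009
_MASK_OFFSET = 1_000_003


def default_taxa(n: int) -> list[str]:
    """Deterministic DNA-voucher-style sample names (NVG-xxxxxLyy)."""
    return [f"NVG-{17001 + 37 * i:05d}{'ABCDEFGH'[i % 8]}{i % 12 + 1:02d}" for i in range(n)]


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_taxa: int = 12
    tree_source: str | float = 1.0  # newick string, or Yule birth rate per lineage
    n_loci: int = 20
    locus_length: int = 300
    subst_model: str = "JC69"
    gtr_rates: tuple[float, ...] = (1.0, 2.0, 1.0, 1.0, 2.0, 1.0)  # AC AG AT CG CT GT
    gtr_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    planted_clade: frozenset[str] = frozenset()
    n_planted: int = 10
    missing_fraction: float = 0.05
    coverage_mean: float = 25.0
    coverage_dispersion: float = 5.0
    taxa: tuple[str, ...] = ()
    include_barcode: bool = True
    locus_prefix: str = "aly"
    tree_scale: float = 0.05  # expected substitutions per site per unit of tree depth

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if not self.taxa:
            object.__setattr__(self, "taxa", tuple(default_taxa(self.n_taxa)))
        if len(self.taxa) != self.n_taxa:
            raise ValueError("taxa list length must equal n_taxa")
        if not self.planted_clade:
            k = max(2, min(self.n_taxa - 1, (self.n_taxa + 2) // 3))
            object.__setattr__(self, "planted_clade", frozenset(self.taxa[:k]))
        object.__setattr__(self, "planted_clade", frozenset(self.planted_clade))
        if not self.planted_clade <= set(self.taxa) or not (
            0 < len(self.planted_clade) < self.n_taxa
        ):
            raise ValueError("planted_clade must be a proper non-empty subset of the taxa")
        if self.subst_model not in ("JC69", "GTR"):
            raise ValueError(f"unknown substitution model {self.subst_model!r}")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage_mean and coverage_dispersion must be > 0")
        total = self.n_loci * self.locus_length
        if self.n_planted > total:
            raise ValueError("n_planted exceeds total alignment length")
        if len(self.gtr_rates) != 6 or min(self.gtr_rates) <= 0:
            raise ValueError("gtr_rates must be 6 positive exchangeabilities")
        freqs = np.asarray(self.gtr_freqs, dtype=float)
        if len(freqs) != 4 or min(freqs) <= 0 or abs(freqs.sum() - 1) > 1e-8:
            raise ValueError("gtr_freqs must be 4 positive frequencies summing to 1")


def rate_matrix(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """(Q, equilibrium frequencies), normalised to one expected substitution
    per site per unit branch length."""
    if config.subst_model == "JC69":
        q = np.full((4, 4), 1.0 / 3.0)
        np.fill_diagonal(q, -1.0)
        return q, np.full(4, 0.25)
    freqs = np.asarray(config.gtr_freqs, dtype=float)
    s = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for rate, (i, j) in zip(config.gtr_rates, pairs):
        s[i, j] = s[j, i] = rate
    q = s * freqs[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(freqs * np.diag(q)).sum()
    return q / mu, freqs


def _yule(names: list[str], rate: float, rng: np.random.Generator) -> TreeNode:
    """Pure-birth tree: lineages split at rate *rate* each until len(names)
    tips exist; every branch accrues the waiting times it lives through."""
    root = TreeNode()
    root.length = 0.0
    active = [root]
    while len(active) < len(names):
        dt = rng.exponential(1.0 / (rate * len(active)))
        for node in active:
            node.length += dt
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        for _ in range(2):
            child = TreeNode()
            child.length = 0.0
            parent.append(child)
            active.append(child)
    dt = rng.exponential(1.0 / (rate * len(active)))
    for node in active:
        node.length += dt
    order = rng.permutation(len(names))
    for tip, k in zip(active, order):
        tip.name = names[k]
    root.length = None
    return root


def simulate_tree(config: SimulationConfig) -> TreeNode:
    """Rooted binary tree over the configured taxa with the planted clade
    constrained to be monophyletic."""
    clade = sorted(config.planted_clade)
    others = sorted(set(config.taxa) - config.planted_clade)
    if not others:
        raise ValueError("planted clade cannot span all taxa")
    if isinstance(config.tree_source, str):
        tree = TreeNode.read([config.tree_source])
        tips = {t.name for t in tree.tips()}
        if tips != set(config.taxa):
            raise ValueError("newick tip labels do not match configured taxa")
        if not is_monophyletic(tree, config.planted_clade):
            raise ValueError("planted clade is not monophyletic in the supplied newick")
        return tree
    rate = float(config.tree_source)
    rng = np.random.default_rng(config.seed)
    placeholder = "__CLADE__"
    backbone = _yule(others + [placeholder], rate, rng)
    if len(clade) == 1:
        backbone.find(placeholder).name = clade[0]
        return backbone
    sub = _yule(clade, rate, rng)
    graft = backbone.find(placeholder)
    graft.name = None
    for child in list(sub.children):
        graft.append(child)  # keeps each child's branch length
    return backbone


def evolve_alignment(tree: TreeNode, config: SimulationConfig) -> AlignmentSet:
    """Evolve one alignment per locus along the tree.

    Each branch applies the transition matrix expm(Q * t * tree_scale); each
    locus uses its own deterministic random stream (seed + locus index).
    """
    tips = {t.name for t in tree.tips()}
    if tips != set(config.taxa):
        raise ValueError("tree leaves do not match configured taxa")
    q, freqs = rate_matrix(config)
    refs = locus_refs(config)
    taxa = list(config.taxa)
    t_index = {t: i for i, t in enumerate(taxa)}
    loci = []
    partition_of = {}
    for locus_idx, (ref, part, length) in enumerate(refs):
        rng = np.random.default_rng(config.seed + locus_idx)
        states = {id(tree): rng.choice(4, size=length, p=freqs)}
        mat = np.empty((len(taxa), length), dtype="<U1")
        for node in tree.preorder(include_self=False):
            t = (node.length or 0.0) * config.tree_scale
            p = expm(q * t)
            cum = np.clip(p.cumsum(axis=1), 0.0, 1.0)
            cum[:, -1] = 1.0
            parent_states = states[id(node.parent)]
            u = rng.random(length)
            child = (u[:, None] > cum[parent_states]).sum(axis=1)
            states[id(node)] = child
            if node.is_tip():
                mat[t_index[node.name]] = BASES[child]
        loci.append((ref, mat))
        partition_of[ref] = part
    return AlignmentSet(taxa=taxa, loci=loci, partition_of=partition_of)


def locus_refs(config: SimulationConfig) -> list[tuple[LocusRef, str, int]]:
    """Deterministic locus addresses and partition labels for one config."""
    out = []
    for i in range(config.n_loci):
        ref = LocusRef(config.locus_prefix, 100 + 13 * i, 1 + (i * 7) % 90, 1 + i % 5)
        part = "Z" if i % 5 == 3 else ("mito" if i % 5 == 4 else "nuclear")
        out.append((ref, part, config.locus_length))
    if config.include_barcode:
        out.append((LocusRef("coi", 1, 1, 1), "coi_barcode", COI_BARCODE_LENGTH))
    return out


def plant_synapomorphies(
    aln: AlignmentSet,
    tree: TreeNode,
    clade: frozenset[str] | set[str],
    n: int,
    seed: int,
    partitions: tuple[str, ...] = ("nuclear", "Z", "mito"),
) -> tuple[AlignmentSet, list[DiagnosticCharacter]]:
    """Overwrite *n* random positions with perfect clade synapomorphies.

    At each chosen position every clade taxon is set to a derived state d and
    every other taxon to an ancestral state a != d, so the ground truth is
    exact by construction.  Returns the modified alignment and the planted
    characters (barcode-partition positions are recorded in 1-658 barcode
    coordinates).
    """
    clade = frozenset(clade)
    if not is_monophyletic(tree, clade):
        raise ValueError("clade is not monophyletic in the tree")
    sites = [
        (ref, pos)
        for ref, mat in aln.loci
        if aln.partition_of[ref] in partitions
        for pos in range(mat.shape[1])
    ]
    if n > len(sites):
        raise ValueError(f"cannot plant {n} synapomorphies in {len(sites)} positions")
    rng = np.random.default_rng(seed + _PLANT_OFFSET)
    chosen = sorted(rng.choice(len(sites), size=n, replace=False).tolist())
    clade_rows = [aln.taxon_index(t) for t in sorted(clade)]
    other_rows = [i for i in range(len(aln.taxa)) if i not in clade_rows]
    new_loci = [(ref, mat.copy()) for ref, mat in aln.loci]
    mats = {ref: mat for ref, mat in new_loci}
    barcode_offsets = None
    if "coi_barcode" in partitions and any(
        aln.partition_of[r] == "coi_barcode" for r in aln.partition_of
    ):
        _, barcode_offsets = concatenate(aln, "coi_barcode")
    truth = []
    for k in chosen:
        ref, pos0 = sites[k]
        a_idx = int(rng.integers(4))
        d_idx = int((a_idx + 1 + rng.integers(3)) % 4)
        a, d = str(BASES[a_idx]), str(BASES[d_idx])
        mats[ref][clade_rows, pos0] = d
        mats[ref][other_rows, pos0] = a
        if aln.partition_of[ref] == "coi_barcode":
            assert barcode_offsets is not None
            col = barcode_offsets.to_column(ref, pos0 + 1)
            truth.append(DiagnosticCharacter(None, col, KIND_DERIVED, a, d))
        else:
            truth.append(DiagnosticCharacter(ref, pos0 + 1, KIND_DERIVED, a, d))
    planted = AlignmentSet(
        taxa=list(aln.taxa),
        loci=new_loci,
        partition_of=dict(aln.partition_of),
        coverage=aln.coverage,
    )
    return planted, truth


def apply_missingness_and_coverage(
    aln: AlignmentSet, config: SimulationConfig
) -> AlignmentSet:
    """Mask cells to 'N' with probability missing_fraction and attach
    negative-binomial read depths (masked cells depth 0, others >= 1)."""
    m, k = config.coverage_mean, config.coverage_dispersion
    p_nb = k / (k + m)
    new_loci = []
    coverage = {}
    for locus_idx, (ref, mat) in enumerate(aln.loci):
        rng = np.random.default_rng(config.seed + _MASK_OFFSET + locus_idx)
        out = mat.copy()
        mask = rng.random(mat.shape) < config.missing_fraction
        out[mask] = "N"
        depth = rng.negative_binomial(k, p_nb, size=mat.shape)
        depth = np.maximum(depth, 1)
        depth[mask] = 0
        new_loci.append((ref, out))
        coverage[ref] = depth
    return AlignmentSet(
        taxa=list(aln.taxa),
        loci=new_loci,
        partition_of=dict(aln.partition_of),
        coverage=coverage,
    )


@dataclass(frozen=True)
class SimulationResult:
    config: SimulationConfig
    tree: TreeNode
    alignment: AlignmentSet
    truth: list[DiagnosticCharacter]


def simulate(config: SimulationConfig) -> SimulationResult:
    """Full generator: tree -> evolved alignment -> planted synapomorphies ->
    missingness and coverage."""
    tree = simulate_tree(config)
    aln = evolve_alignment(tree, config)
    aln, truth = plant_synapomorphies(
        aln, tree, config.planted_clade, config.n_planted, config.seed
    )
    aln = apply_missingness_and_coverage(aln, config)
    return SimulationResult(config=config, tree=tree, alignment=aln, truth=truth)


def default_clade_partition(config: SimulationConfig) -> CladePartition:
    """Focal = planted clade, outgroups = everything else."""
    return CladePartition(
        focal=config.planted_clade,
        outgroups=frozenset(config.taxa) - config.planted_clade,
    )


def write_outputs(result: SimulationResult, out_dir: str | Path) -> Path:
    """Write FASTAs, manifest, coverage table, ground-truth characters (in
    notation format), the true tree, and the default clade definition."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_alignments(result.alignment, out_dir)
    write_newick(result.tree, out_dir / "true_tree.nwk")
    (out_dir / "ground_truth.txt").write_text(
        "".join(render(ch) + "\n" for ch in result.truth)
    )
    write_clades(default_clade_partition(result.config), out_dir / "clades.txt")
    return out_dir
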