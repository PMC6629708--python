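"""End-to-end run: simulate -> scan -> barcode distances -> trees -> rank.

Every randomized stage derives its stream from the single run seed, so a
rerun with the same config is byte-identical.  Each run directory contains
the simulated inputs, every stage's outputs, a machine-readable summary and
a log of parameters and seeds.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .alignio import AlignmentSet, CladePartition, concatenate, read_flat_config
from .charscan import ScanParams, audit_table, scan_barcode, scan_clade, scan_singleton
from .distbar import associate_specimens, distance_matrix
from .notation import render
from .simdata import SimulationConfig, SimulationResult, simulate, write_outputs
from .treesupport import (
    bootstrap_support,
    build_support_report,
    clades_of,
    rank_decision,
    report_to_dict,
    write_newick,
)

log = logging.getLogger("synapodiag")

TREE_PARTITIONS = ("nuclear", "Z", "mito")


@dataclass(frozen=True)
class RunConfig:
    """Flat parameter set for one pipeline run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    scan: ScanParams = field(default_factory=ScanParams)
    conspecific_threshold: float = 0.02
    n_replicates: int = 100
    strong_threshold: float = 95.0

    @property
    def seed(self) -> int:
        return self.sim.seed


_SIM_KEYS = {
    "seed": int,
    "n_taxa": int,
    "n_loci": int,
    "locus_length": int,
    "subst_model": str,
    "n_planted": int,
    "missing_fraction": float,
    "coverage_mean": float,
    "coverage_dispersion": float,
    "tree_scale": float,
}
_SCAN_KEYS = {
    "outgroup_majority_threshold": float,
    "forbid_derived_in_outgroup": lambda s: s.lower() in ("1", "true", "yes"),
    "max_focal_missing": int,
    "top_k": int,
}
_RUN_KEYS = {
    "conspecific_threshold": float,
    "n_replicates": int,
    "strong_threshold": float,
}


def load_run_config(path: str | Path) -> RunConfig:
    """Flat ``key = value`` run config; 'seed' is mandatory."""
    kv = read_flat_config(path)
    if "seed" not in kv:
        raise ValueError(f"{path}: config must set 'seed'")
    sim_kwargs, scan_kwargs, run_kwargs = {}, {}, {}
    for key, value in kv.items():
        if key in _SIM_KEYS:
            sim_kwargs[key] = _SIM_KEYS[key](value)
        elif key == "birth_rate":
            sim_kwargs["tree_source"] = float(value)
        elif key == "newick":
            sim_kwargs["tree_source"] = value
        elif key == "planted_clade":
            sim_kwargs["planted_clade"] = frozenset(
                t.strip() for t in value.split(",") if t.strip()
            )
        elif key in _SCAN_KEYS:
            scan_kwargs[key] = _SCAN_KEYS[key](value)
        elif key in _RUN_KEYS:
            run_kwargs[key] = _RUN_KEYS[key](value)
        else:
            raise ValueError(f"{path}: unknown config key {key!r}")
    return RunConfig(
        sim=SimulationConfig(**sim_kwargs), scan=ScanParams(**scan_kwargs), **run_kwargs
    )


def _barcode_sequences(aln: AlignmentSet) -> dict[str, str]:
    matrix, _ = concatenate(aln, "coi_barcode")
    return {taxon: "".join(matrix[i]) for i, taxon in enumerate(aln.taxa)}


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute every stage; returns the run directory.

    Any stage failure aborts with the stage name in the exception message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed}
    outputs: list[str] = []

    def stage(name):
        log.info("stage %s", name)

        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    # 1. simulate
    result: SimulationResult = stage("simulate")(lambda: simulate(config.sim))
    sim_dir = out / "sim"
    write_outputs(result, sim_dir)
    outputs += [str(p.relative_to(out)) for p in sorted(sim_dir.iterdir())]
    aln = result.alignment
    focal = config.sim.planted_clade
    outgroups = frozenset(config.sim.taxa) - focal
    clades = CladePartition(focal=focal, outgroups=outgroups)

    # 2. scan: clade mode, barcode mode, and singleton mode for one clade member
    def do_scan():
        chars = scan_clade(aln, clades, config.scan)
        bchars = scan_barcode(aln, clades, config.scan)
        singleton_taxon = min(focal)
        singleton = CladePartition(
            focal=frozenset({singleton_taxon}),
            sister=focal - {singleton_taxon},
            parent_outgroup=outgroups,
            outgroups=outgroups,
        )
        schars = scan_singleton(aln, singleton, config.scan) if len(focal) > 1 else []
        return chars, bchars, schars

    chars, bchars, schars = stage("scan")(do_scan)
    (out / "characters.txt").write_text("".join(render(c) + "\n" for c in chars))
    (out / "barcode_characters.txt").write_text("".join(render(c) + "\n" for c in bchars))
    (out / "singleton_characters.txt").write_text("".join(render(c) + "\n" for c in schars))
    audit = audit_table(aln, clades, config.scan)
    audit.to_csv(out / "scan_audit.tsv", sep="\t", index=False)
    outputs += ["characters.txt", "barcode_characters.txt", "singleton_characters.txt",
                "scan_audit.tsv"]
    summary["n_characters"] = len(chars)
    summary["n_barcode_characters"] = len(bchars)
    summary["n_singleton_characters"] = len(schars)

    # 3. barcode distances and specimen association
    def do_distance():
        dm = distance_matrix(_barcode_sequences(aln))
        assoc = associate_specimens(dm, config.conspecific_threshold)
        return dm, assoc

    dm, assoc = stage("distance")(do_distance)
    dm.to_csv(out / "barcode_distances.tsv", sep="\t")
    (out / "specimen_groups.json").write_text(
        json.dumps(
            {
                "threshold": config.conspecific_threshold,
                "groups": [list(g) for g in assoc.groups],
                "between_group_min": {
                    f"{a}-{b}": d for (a, b), d in sorted(assoc.between_group_min.items())
                },
            },
            indent=2,
        )
        + "\n"
    )
    outputs += ["barcode_distances.tsv", "specimen_groups.json"]
    summary["n_specimen_groups"] = len(assoc.groups)

    # 4. bootstrapped NJ trees per partition.  The rank rule's reference
    # clades come from the true simulated tree: inclusion = the focal clade's
    # parent clade, exclusion = the focal clade's true sister group.  Trees
    # must be rooted outside the inclusion clade or it could never appear.
    true_tree = result.tree
    mrca = true_tree.lca(sorted(focal))
    parent = mrca.parent if mrca.parent is not None else mrca
    inclusion = frozenset(t.name for t in parent.tips())
    exclusion = inclusion - focal
    outside = sorted(frozenset(config.sim.taxa) - inclusion)
    root_taxon = outside[0] if outside else max(outgroups)
    trees = {}
    for i, part in enumerate(TREE_PARTITIONS):
        def do_tree(part=part, i=i):
            matrix, _ = concatenate(aln, part)
            return bootstrap_support(
                matrix, aln.taxa, config.n_replicates,
                seed=config.seed + 7919 * (i + 1), outgroup=root_taxon,
            )
        tree, supports = stage(f"tree[{part}]")(do_tree)
        trees[part] = (tree, supports)
        write_newick(tree, out / f"tree_{part}.nwk")
        outputs.append(f"tree_{part}.nwk")
        summary[f"focal_support_{part}"] = supports.get(frozenset(focal), 0.0)

    # 5. rank decision against the reference clades
    def do_rank():
        report = build_support_report(
            trees, focal=focal, inclusion=inclusion, exclusion=exclusion
        )
        return report, rank_decision(report, config.strong_threshold)

    report, decision = stage("rank")(do_rank)
    (out / "rank_decision.json").write_text(
        json.dumps(
            {
                "report": report_to_dict(report),
                "strong_threshold": config.strong_threshold,
                "scenario": decision.scenario,
                "recommendation": decision.recommendation,
                "rationale": list(decision.rationale),
            },
            indent=2,
        )
        + "\n"
    )
    outputs.append("rank_decision.json")
    summary["recommendation"] = decision.recommendation

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (out / "outputs.txt").write_text("".join(o + "\n" for o in sorted(outputs)) )
    log.info("run complete: %s", out)
    return out
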