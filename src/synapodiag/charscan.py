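"""Clade-diagnostic character scanning.

A position is a candidate synapomorphy for a focal clade when every focal
taxon with data carries the same state *d*, the outgroups are mostly
invariant for a different state *a* (majority frequency at or above a
threshold), and — in strict mode — no outgroup taxon carries *d* at all.
Candidates are ranked by the number of focal taxa with missing data
(fewer is better), then by the weakest-link read depth across the focal
clade (higher is better), then by locus order and position.

When a clade has a single sequenced representative, a direct scan is
uninformative (any private state would qualify), so the singleton strategy
combines (a) positions where the *sister* clade carries a synapomorphy that
the focal taxon does not share — reported as "ancestral (not sister-state)"
characters — with (b) synapomorphies of the focal+sister clade against the
outgroup of their common ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .alignio import (
    AMBIGUITY_SYMBOLS,
    AlignmentSet,
    CladePartition,
    LocusRef,
    concatenate,
    is_certain_base,
)
from .notation import (
    KIND_DERIVED,
    KIND_RETAINED_NOT,
    KIND_STATE_ONLY,
    DiagnosticCharacter,
)


@dataclass(frozen=True)
class ScanParams:
    """Tunable thresholds of the scan.

    outgroup_majority_threshold
        Minimum frequency of the modal outgroup state among non-missing
        outgroup taxa for that state to count as the (mostly invariant)
        ancestral state; in (0.5, 1].
    forbid_derived_in_outgroup
        Strict mode: reject a candidate if any outgroup taxon carries the
        focal clade's state.
    max_focal_missing
        Maximum focal taxa allowed to lack data at a reported position;
        ``None`` means |focal| - 1 (at least one focal observation).
    top_k
        Number of ranked characters to report.
    """

    outgroup_majority_threshold: float = 0.9
    forbid_derived_in_outgroup: bool = True
    max_focal_missing: int | None = None
    top_k: int = 6

    def __post_init__(self) -> None:
        if not 0.5 < self.outgroup_majority_threshold <= 1.0:
            raise ValueError("outgroup_majority_threshold must be in (0.5, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.max_focal_missing is not None and self.max_focal_missing < 0:
            raise ValueError("max_focal_missing must be >= 0")


class ColumnStatus(Enum):
    CANDIDATE = "candidate"
    REJECTED = "rejected"
    UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class ColumnResult:
    """Outcome of classifying one column, with the rule clause that decided it."""

    status: ColumnStatus
    reason: str
    kind: str | None = None
    ancestral: str | None = None
    derived: str | None = None
    missing_count: int = 0


def _split_observed(states: Sequence[str]) -> tuple[list[str], int]:
    """Partition states into definite bases and a missing count.

    'N', '-', '?' and IUPAC ambiguity codes all count as missing for
    scanning purposes.
    """
    observed = [s for s in states if is_certain_base(s)]
    return observed, len(states) - len(observed)


def classify_column(
    focal_states: Sequence[str],
    outgroup_states: Sequence[str],
    params: ScanParams = ScanParams(),
) -> ColumnResult:
    """Apply the synapomorphy rule clauses to a single alignment column."""
    focal_obs, focal_missing = _split_observed(focal_states)
    out_obs, _ = _split_observed(outgroup_states)
    if not focal_obs or not out_obs:
        return ColumnResult(ColumnStatus.UNINFORMATIVE, "no data in focal or outgroup set")

    derived_states = set(focal_obs)
    if len(derived_states) > 1:
        return ColumnResult(ColumnStatus.REJECTED, "focal clade not invariant")
    d = focal_obs[0]

    counts: dict[str, int] = {}
    for s in out_obs:
        counts[s] = counts.get(s, 0) + 1
    modal_state, modal_n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    majority = modal_n / len(out_obs)

    if majority >= params.outgroup_majority_threshold:
        a = modal_state
        if a == d:
            return ColumnResult(ColumnStatus.REJECTED, "focal state equals outgroup majority")
        if params.forbid_derived_in_outgroup and d in counts:
            return ColumnResult(ColumnStatus.REJECTED, "derived state present in outgroup")
        return ColumnResult(
            ColumnStatus.CANDIDATE, "derived synapomorphy",
            kind=KIND_DERIVED, ancestral=a, derived=d, missing_count=focal_missing,
        )

    # No qualifying majority: the ancestor cannot be polarised.  The focal
    # state is still diagnostic if no outgroup taxon carries it at all.
    if d not in counts:
        return ColumnResult(
            ColumnStatus.CANDIDATE, "focal state absent from outgroup, ancestor unclear",
            kind=KIND_STATE_ONLY, ancestral=None, derived=d, missing_count=focal_missing,
        )
    return ColumnResult(ColumnStatus.REJECTED, "no qualifying outgroup majority state")


def _focal_min_coverage(
    aln: AlignmentSet, ref: LocusRef, col0: int, focal_rows: Sequence[int]
) -> int | None:
    """Weakest-link depth: minimum over focal taxa that have data here."""
    if aln.coverage is None or ref not in aln.coverage:
        return None
    mat = aln.matrix(ref)
    depths = [
        int(aln.coverage[ref][i, col0])
        for i in focal_rows
        if is_certain_base(mat[i, col0])
    ]
    return min(depths) if depths else 0


def _rank_key(aln: AlignmentSet, ch: DiagnosticCharacter) -> tuple:
    order = {ref: i for i, ref in enumerate(aln.locus_refs)}
    locus_order = order.get(ch.locus, len(order)) if ch.locus is not None else len(order)
    cov = ch.min_coverage if ch.min_coverage is not None else 0
    return (ch.missing_count, -cov, locus_order, ch.position)


def rank_characters(
    aln: AlignmentSet, chars: Iterable[DiagnosticCharacter], top_k: int
) -> list[DiagnosticCharacter]:
    return sorted(chars, key=lambda ch: _rank_key(aln, ch))[:top_k]


def _scan_matrix(
    aln: AlignmentSet,
    refs_and_mats: list[tuple[LocusRef | None, np.ndarray]],
    focal: frozenset[str],
    outgroups: frozenset[str],
    params: ScanParams,
    barcode_refs: dict[int, tuple[LocusRef, int]] | None = None,
) -> list[DiagnosticCharacter]:
    focal_rows = [aln.taxon_index(t) for t in sorted(focal)]
    out_rows = [aln.taxon_index(t) for t in sorted(outgroups)]
    max_missing = (
        params.max_focal_missing
        if params.max_focal_missing is not None
        else len(focal_rows) - 1
    )
    found: list[DiagnosticCharacter] = []
    for ref, mat in refs_and_mats:
        for col0 in range(mat.shape[1]):
            res = classify_column(mat[focal_rows, col0], mat[out_rows, col0], params)
            if res.status is not ColumnStatus.CANDIDATE or res.missing_count > max_missing:
                continue
            if ref is None:  # barcode coordinates; coverage keyed by source locus
                cov = None
                if barcode_refs is not None and aln.coverage is not None:
                    src_ref, src_col0 = barcode_refs[col0]
                    cov = _focal_min_coverage(aln, src_ref, src_col0, focal_rows)
                ch = DiagnosticCharacter(
                    None, col0 + 1, res.kind, res.ancestral, res.derived,
                    missing_count=res.missing_count, min_coverage=cov,
                )
            else:
                ch = DiagnosticCharacter(
                    ref, col0 + 1, res.kind, res.ancestral, res.derived,
                    missing_count=res.missing_count,
                    min_coverage=_focal_min_coverage(aln, ref, col0, focal_rows),
                )
            found.append(ch)
    return found


def scan_clade(
    aln: AlignmentSet,
    clades: CladePartition,
    params: ScanParams = ScanParams(),
    partitions: Sequence[str] = ("nuclear", "Z", "mito"),
) -> list[DiagnosticCharacter]:
    """Scan every column of the given partitions for focal-clade
    synapomorphies; returns the ranked top_k characters."""
    refs_and_mats = [
        (ref, mat) for ref, mat in aln.loci if aln.partition_of[ref] in partitions
    ]
    found = _scan_matrix(aln, refs_and_mats, clades.focal, clades.outgroups, params)
    return rank_characters(aln, found, params.top_k)


def scan_singleton(
    aln: AlignmentSet,
    clades: CladePartition,
    params: ScanParams = ScanParams(),
    partitions: Sequence[str] = ("nuclear", "Z", "mito"),
) -> list[DiagnosticCharacter]:
    """Diagnose a clade with a single sequenced species via its sister.

    Returns the ranked union of (a) "retained" characters: sister-clade
    synapomorphies the focal taxon does not share, and (b) synapomorphies of
    focal+sister against the parent clade's outgroup.
    """
    if len(clades.focal) != 1:
        raise ValueError("scan_singleton requires exactly one focal taxon")
    if not clades.sister:
        raise ValueError("scan_singleton requires a sister taxon set")
    if not clades.parent_outgroup:
        raise ValueError("scan_singleton requires a parent_outgroup taxon set")
    (focal_taxon,) = clades.focal
    focal_row = aln.taxon_index(focal_taxon)
    wide = ScanParams(
        outgroup_majority_threshold=params.outgroup_majority_threshold,
        forbid_derived_in_outgroup=params.forbid_derived_in_outgroup,
        max_focal_missing=None,
        top_k=max(params.top_k, 10 * params.top_k),
    )

    # (a) sister synapomorphies not shared by the focal taxon
    sister_clades = CladePartition(focal=clades.sister, outgroups=clades.outgroups)
    retained: list[DiagnosticCharacter] = []
    for ch in scan_clade(aln, sister_clades, wide, partitions):
        if ch.kind != KIND_DERIVED or ch.locus is None:
            continue
        state = aln.matrix(ch.locus)[focal_row, ch.position - 1]
        if not is_certain_base(state):
            continue  # focal taxon missing here: cannot claim retention
        if state == ch.ancestral:
            retained.append(
                DiagnosticCharacter(
                    ch.locus, ch.position, KIND_RETAINED_NOT, ch.ancestral, ch.derived,
                    missing_count=0,
                    min_coverage=_focal_min_coverage(
                        aln, ch.locus, ch.position - 1, [focal_row]
                    ),
                )
            )
        # state == derived or a third state: not distinguishable as retained

    # (b) synapomorphies of the parent clade (focal + sister)
    parent_clades = CladePartition(
        focal=clades.focal | clades.sister, outgroups=clades.parent_outgroup
    )
    parent_chars = scan_clade(aln, parent_clades, wide, partitions)

    merged: dict[tuple, DiagnosticCharacter] = {}
    for ch in list(retained) + list(parent_chars):
        merged.setdefault(ch.identity(), ch)
    return rank_characters(aln, merged.values(), params.top_k)


def scan_barcode(
    aln: AlignmentSet,
    clades: CladePartition,
    params: ScanParams = ScanParams(),
) -> list[DiagnosticCharacter]:
    """Scan the 658-position COI barcode region; characters carry barcode
    coordinates (1-658) and no locus prefix."""
    matrix, offsets = concatenate(aln, "coi_barcode")
    barcode_refs = {
        col: offsets.to_locus(col + 1) for col in range(matrix.shape[1])
    }
    barcode_refs = {c: (ref, pos - 1) for c, (ref, pos) in barcode_refs.items()}
    found = _scan_matrix(
        aln, [(None, matrix)], clades.focal, clades.outgroups, params,
        barcode_refs=barcode_refs,
    )
    max_missing = (
        params.max_focal_missing
        if params.max_focal_missing is not None
        else len(clades.focal) - 1
    )
    found = [ch for ch in found if ch.missing_count <= max_missing]
    return rank_characters(aln, found, params.top_k)


def audit_table(
    aln: AlignmentSet,
    clades: CladePartition,
    params: ScanParams = ScanParams(),
    partitions: Sequence[str] = ("nuclear", "Z", "mito"),
):
    """Per-column audit of the rule outcomes (pandas DataFrame): locus,
    position, focal/outgroup state summaries, missing counts on both sides,
    minimum focal coverage and the deciding clause."""
    import pandas as pd

    focal_rows = [aln.taxon_index(t) for t in sorted(clades.focal)]
    out_rows = [aln.taxon_index(t) for t in sorted(clades.outgroups)]
    rows = []
    for ref, mat in aln.loci:
        if aln.partition_of[ref] not in partitions:
            continue
        for col0 in range(mat.shape[1]):
            fstates = mat[focal_rows, col0]
            ostates = mat[out_rows, col0]
            res = classify_column(fstates, ostates, params)
            _, out_missing = _split_observed(ostates)
            rows.append(
                dict(
                    locus=str(ref),
                    position=col0 + 1,
                    focal_states="".join(fstates),
                    outgroup_states="".join(ostates),
                    outgroup_missing=out_missing,
                    status=res.status.value,
                    reason=res.reason,
                    kind=res.kind or "",
                    ancestral=res.ancestral or "",
                    derived=res.derived or "",
                    missing_count=res.missing_count,
                    min_coverage=_focal_min_coverage(aln, ref, col0, focal_rows),
                )
            )
    return pd.DataFrame(rows)
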