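"""Partitioned alignment IO and addressing.

Alignments are organised per locus, where a locus is one exon of one gene on
one scaffold of a reference genome, addressed as ``<prefix><scaffold>.<gene>.<exon>``
(e.g. ``aly728.44.1`` = exon 1 of gene 44 on scaffold 728 of the *Cecropterus
lyciades* reference).  Each locus belongs to one genome partition: nuclear
autosome, Z chromosome, mitogenome, or the 658-bp COI barcode region.

Coordinates are 1-based and closed within each exon.  Missing data may be
encoded as ``N``, ``-`` or ``?`` (preserved verbatim for round-trips); IUPAC
ambiguity codes are kept in the matrix but treated as missing by consumers
that need a definite base (see :func:`is_certain_base`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PARTITIONS = ("nuclear", "Z", "mito", "coi_barcode")
COI_BARCODE_LENGTH = 658

MISSING_SYMBOLS = frozenset("N-?")
AMBIGUITY_SYMBOLS = frozenset("RYSWKMBDHV")
BASES = ("A", "C", "G", "T")
_BASE_SET = frozenset(BASES)

_CERTAIN = frozenset(BASES)


def is_certain_base(state: str) -> bool:
    """True if *state* is an unambiguous nucleotide (A/C/G/T)."""
    return state in _CERTAIN


class AlignmentError(ValueError):
    """Malformed alignment input (length mismatch, duplicate taxon, ...)."""


_LOCUS_RE = re.compile(r"^([a-z]+)(\d+)\.(\d+)\.(\d+)$")


@dataclass(frozen=True, order=True)
class LocusRef:
    """Address of one exon in the reference genome: prefix + scaffold.gene.exon."""

    prefix: str
    scaffold: int
    gene: int
    exon: int

    def __post_init__(self) -> None:
        if not self.prefix or not self.prefix.isalpha() or not self.prefix.islower():
            raise ValueError(f"locus prefix must be lowercase letters, got {self.prefix!r}")
        if min(self.scaffold, self.gene, self.exon) < 0:
            raise ValueError("scaffold/gene/exon must be non-negative")

    def __str__(self) -> str:
        return f"{self.prefix}{self.scaffold}.{self.gene}.{self.exon}"

    @classmethod
    def parse(cls, text: str) -> "LocusRef":
        m = _LOCUS_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse locus id {text!r} (expected e.g. 'aly728.44.1')")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)), int(m.group(4)))


@dataclass(frozen=True)
class CladePartition:
    """Taxon sets defining one diagnosis: focal clade, optional sister,
    outgroup for the parent clade, and outgroups for the focal comparison."""

    focal: frozenset[str]
    outgroups: frozenset[str]
    sister: frozenset[str] | None = None
    parent_outgroup: frozenset[str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "focal", frozenset(self.focal))
        object.__setattr__(self, "outgroups", frozenset(self.outgroups))
        if self.sister is not None:
            object.__setattr__(self, "sister", frozenset(self.sister))
        if self.parent_outgroup is not None:
            object.__setattr__(self, "parent_outgroup", frozenset(self.parent_outgroup))
        if not self.focal:
            raise ValueError("focal clade must be non-empty")
        if not self.outgroups:
            raise ValueError("outgroup set must be non-empty")
        if self.focal & self.outgroups:
            raise ValueError("focal and outgroup taxon sets must be disjoint")
        if self.sister is not None and (not self.sister or self.sister & self.focal):
            raise ValueError("sister set must be non-empty and disjoint from focal")


@dataclass
class AlignmentSet:
    """Ordered per-locus nucleotide matrices plus partition metadata.

    ``loci`` holds ``(LocusRef, matrix)`` pairs where matrix is a 2-D array of
    single characters with one row per taxon in ``taxa`` order.  ``coverage``
    (optional) maps each locus to an integer depth matrix of the same shape.
    """

    taxa: list[str]
    loci: list[tuple[LocusRef, np.ndarray]]
    partition_of: dict[LocusRef, str]
    coverage: dict[LocusRef, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon names")
        for ref, mat in self.loci:
            if mat.shape[0] != len(self.taxa):
                raise AlignmentError(f"locus {ref}: {mat.shape[0]} rows for {len(self.taxa)} taxa")
            part = self.partition_of.get(ref)
            if part not in PARTITIONS:
                raise AlignmentError(f"locus {ref}: unknown partition {part!r}")
        if self.coverage is not None:
            for ref, mat in self.loci:
                cov = self.coverage.get(ref)
                if cov is not None and cov.shape != mat.shape:
                    raise AlignmentError(f"locus {ref}: coverage shape {cov.shape} != {mat.shape}")

    @property
    def locus_refs(self) -> list[LocusRef]:
        return [ref for ref, _ in self.loci]

    def matrix(self, ref: LocusRef) -> np.ndarray:
        for r, mat in self.loci:
            if r == ref:
                return mat
        raise KeyError(str(ref))

    def taxon_index(self, name: str) -> int:
        try:
            return self.taxa.index(name)
        except ValueError:
            raise KeyError(f"unknown taxon {name!r}") from None


@dataclass(frozen=True)
class OffsetMap:
    """Bijection between concatenated 1-based columns and (locus, position)."""

    starts: tuple[tuple[LocusRef, int], ...]  # (locus, 1-based start column), in order
    lengths: Mapping[LocusRef, int]

    def start_of(self, ref: LocusRef) -> int:
        for r, s in self.starts:
            if r == ref:
                return s
        raise KeyError(str(ref))

    def to_locus(self, column: int) -> tuple[LocusRef, int]:
        """Concatenated column -> (locus, within-exon 1-based position)."""
        for ref, start in reversed(self.starts):
            if column >= start:
                pos = column - start + 1
                if pos > self.lengths[ref]:
                    break
                return ref, pos
        raise IndexError(f"column {column} outside concatenated range")

    def to_column(self, ref: LocusRef, position: int) -> int:
        if not 1 <= position <= self.lengths[ref]:
            raise IndexError(f"position {position} outside locus {ref}")
        return self.start_of(ref) + position - 1


def read_alignments(
    manifest_path: str | Path,
    fasta_dir: str | Path,
    coverage_path: str | Path | None = None,
) -> AlignmentSet:
    """Read a partition manifest plus one FASTA per locus into an AlignmentSet.

    The manifest is tab-separated with columns
    ``locus_id  scaffold  gene  exon  partition  length``; each ``locus_id``
    must have a matching ``<locus_id>.fasta`` in *fasta_dir*.  Lowercase
    sequence is uppercased; taxa absent from a locus are added as all-missing
    (``N``) rows so every locus shares the same taxon set.
    """
    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str)
    required = {"locus_id", "partition", "length"}
    if not required <= set(manifest.columns):
        raise AlignmentError(f"manifest must have columns {sorted(required)}")

    fasta_dir = Path(fasta_dir)
    raw: list[tuple[LocusRef, dict[str, str]]] = []
    partition_of: dict[LocusRef, str] = {}
    taxa_order: list[str] = []
    for row in manifest.itertuples(index=False):
        ref = LocusRef.parse(row.locus_id)
        part = row.partition
        if part not in PARTITIONS:
            raise AlignmentError(f"locus {ref}: unknown partition {part!r}")
        length = int(row.length)
        path = fasta_dir / f"{ref}.fasta"
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise AlignmentError(f"locus {ref}: duplicate taxon {rec.id!r}")
            seq = str(rec.seq).upper()
            if len(seq) != length:
                raise AlignmentError(
                    f"locus {ref}, taxon {rec.id!r}: length {len(seq)} != manifest {length}"
                )
            seqs[rec.id] = seq
            if rec.id not in taxa_order:
                taxa_order.append(rec.id)
        if not seqs:
            raise AlignmentError(f"locus {ref}: no sequences in {path}")
        raw.append((ref, seqs))
        partition_of[ref] = part

    loci = []
    for ref, seqs in raw:
        length = len(next(iter(seqs.values())))
        mat = np.full((len(taxa_order), length), "N", dtype="<U1")
        for i, taxon in enumerate(taxa_order):
            if taxon in seqs:
                mat[i] = list(seqs[taxon])
        loci.append((ref, mat))

    coverage = None
    if coverage_path is not None:
        coverage = read_coverage(coverage_path, taxa_order, loci)
    return AlignmentSet(taxa=taxa_order, loci=loci, partition_of=partition_of, coverage=coverage)


def write_alignments(aln: AlignmentSet, out_dir: str | Path) -> Path:
    """Write one FASTA per locus plus the tab-separated manifest; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ref, mat in aln.loci:
        records = [
            SeqRecord(Seq("".join(mat[i])), id=taxon, description="")
            for i, taxon in enumerate(aln.taxa)
        ]
        SeqIO.write(records, str(out_dir / f"{ref}.fasta"), "fasta")
        rows.append(
            dict(
                locus_id=str(ref),
                scaffold=ref.scaffold,
                gene=ref.gene,
                exon=ref.exon,
                partition=aln.partition_of[ref],
                length=mat.shape[1],
            )
        )
    manifest_path = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    if aln.coverage is not None:
        write_coverage(aln, out_dir / "coverage.tsv")
    return manifest_path


def read_coverage(
    path: str | Path,
    taxa: list[str],
    loci: list[tuple[LocusRef, np.ndarray]],
) -> dict[LocusRef, np.ndarray]:
    """Read the long-format coverage table (taxon, locus_id, position, depth).

    Cells absent from the table get depth 0.
    """
    table = pd.read_csv(path, sep="\t", dtype={"taxon": str, "locus_id": str})
    cov = {ref: np.zeros(mat.shape, dtype=int) for ref, mat in loci}
    by_id = {str(ref): ref for ref, _ in loci}
    t_index = {t: i for i, t in enumerate(taxa)}
    for row in table.itertuples(index=False):
        ref = by_id.get(row.locus_id)
        if ref is None:
            raise AlignmentError(f"coverage table references unknown locus {row.locus_id!r}")
        cov[ref][t_index[row.taxon], int(row.position) - 1] = int(row.depth)
    return cov


def write_coverage(aln: AlignmentSet, path: str | Path) -> None:
    assert aln.coverage is not None
    recs = []
    for ref, _ in aln.loci:
        depth = aln.coverage[ref]
        for i, taxon in enumerate(aln.taxa):
            nonzero = np.nonzero(depth[i])[0]
            for j in nonzero:
                recs.append((taxon, str(ref), j + 1, int(depth[i, j])))
    pd.DataFrame(recs, columns=["taxon", "locus_id", "position", "depth"]).to_csv(
        path, sep="\t", index=False
    )


def read_clades(path: str | Path) -> CladePartition:
    """Read a clade-definition file: flat ``role = taxon1, taxon2, ...`` lines
    with roles focal / sister / parent_outgroup / outgroups."""
    kv = read_flat_config(path)
    def names(key: str) -> frozenset[str] | None:
        if key not in kv or not kv[key].strip():
            return None
        return frozenset(t.strip() for t in kv[key].split(",") if t.strip())
    focal, outgroups = names("focal"), names("outgroups")
    if focal is None or outgroups is None:
        raise AlignmentError("clade file must define 'focal' and 'outgroups'")
    return CladePartition(
        focal=focal,
        outgroups=outgroups,
        sister=names("sister"),
        parent_outgroup=names("parent_outgroup"),
    )


def write_clades(clades: CladePartition, path: str | Path) -> None:
    lines = [f"focal = {', '.join(sorted(clades.focal))}"]
    if clades.sister:
        lines.append(f"sister = {', '.join(sorted(clades.sister))}")
    if clades.parent_outgroup:
        lines.append(f"parent_outgroup = {', '.join(sorted(clades.parent_outgroup))}")
    lines.append(f"outgroups = {', '.join(sorted(clades.outgroups))}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_flat_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` config; '#' starts a comment; later keys win."""
    kv: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise AlignmentError(f"{path}:{lineno}: expected 'key = value'")
        key, value = line.split("=", 1)
        kv[key.strip()] = value.strip()
    return kv


def extract_region(aln: AlignmentSet, partition: str) -> AlignmentSet:
    """Restrict to one partition, preserving locus order.

    For ``coi_barcode`` the concatenated length of the result is the standard
    658 positions.
    """
    if partition not in PARTITIONS:
        raise AlignmentError(f"unknown partition {partition!r}")
    keep = [(ref, mat) for ref, mat in aln.loci if aln.partition_of[ref] == partition]
    if not keep:
        raise AlignmentError(f"no loci in partition {partition!r}")
    refs = {ref for ref, _ in keep}
    coverage = None
    if aln.coverage is not None:
        coverage = {ref: aln.coverage[ref] for ref in refs if ref in aln.coverage}
    return AlignmentSet(
        taxa=list(aln.taxa),
        loci=keep,
        partition_of={ref: partition for ref in refs},
        coverage=coverage,
    )


def concatenate(aln: AlignmentSet, partition: str) -> tuple[np.ndarray, OffsetMap]:
    """Concatenate all loci of one partition into a single taxa x columns
    matrix, plus the offset map back to (locus, within-exon position)."""
    sub = extract_region(aln, partition)
    starts = []
    lengths: dict[LocusRef, int] = {}
    col = 1
    for ref, mat in sub.loci:
        starts.append((ref, col))
        lengths[ref] = mat.shape[1]
        col += mat.shape[1]
    matrix = np.concatenate([mat for _, mat in sub.loci], axis=1)
    return matrix, OffsetMap(starts=tuple(starts), lengths=lengths)
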