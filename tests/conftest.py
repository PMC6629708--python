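import numpy as np
import pytest

from synapodiag.alignio import AlignmentSet, CladePartition, LocusRef


def make_alignment(taxa, locus_specs, coverage=None):
    """Build an AlignmentSet from {LocusRef or 'id-string': {partition, rows}}.

    ``rows`` is a list of equal-length sequence strings in *taxa* order.
    """
    loci = []
    partition_of = {}
    cov = {} if coverage else None
    for key, spec in locus_specs.items():
        ref = key if isinstance(key, LocusRef) else LocusRef.parse(key)
        mat = np.array([list(row) for row in spec["rows"]], dtype="<U1")
        loci.append((ref, mat))
        partition_of[ref] = spec.get("partition", "nuclear")
        if coverage and ref in coverage:
            cov[ref] = np.asarray(coverage[ref], dtype=int)
        elif coverage:
            cov[ref] = np.full(mat.shape, 10, dtype=int)
    return AlignmentSet(taxa=list(taxa), loci=loci, partition_of=partition_of, coverage=cov)


@pytest.fixture
def four_vs_outgroup():
    """Tiny hand-built alignment: 3 focal taxa, 4 outgroups, one nuclear locus."""
    taxa = ["f1", "f2", "f3", "o1", "o2", "o3", "o4"]
    rows = [
        "CAGTA",
        "CAGTA",
        "CAGTA",
        "GAGTA",
        "GAGTA",
        "GAGTA",
        "GAGTA",
    ]
    aln = make_alignment(taxa, {"aly10.1.1": {"rows": rows}})
    clades = CladePartition(focal=frozenset(taxa[:3]), outgroups=frozenset(taxa[3:]))
    return aln, clades
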