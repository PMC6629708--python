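"""Synapomorphy scanning: rule clauses, ranking, singleton strategy, oracle."""

import numpy as np
import pytest

from conftest import make_alignment
from oracle import brute_force_scan
from synapodiag.alignio import CladePartition, LocusRef
from synapodiag.charscan import (
    ColumnStatus,
    ScanParams,
    audit_table,
    classify_column,
    scan_barcode,
    scan_clade,
    scan_singleton,
)
from synapodiag.notation import KIND_RETAINED_NOT, KIND_STATE_ONLY, render

STRICT = ScanParams(outgroup_majority_threshold=1.0, forbid_derived_in_outgroup=True)


class TestClassifyColumn:
    def test_perfect_synapomorphy(self):
        res = classify_column(list("CCC"), list("GGGG"), STRICT)
        assert res.status is ColumnStatus.CANDIDATE
        assert (res.ancestral, res.derived, res.missing_count) == ("G", "C", 0)

    def test_focal_missing_counts_but_does_not_break_invariance(self):
        res = classify_column(list("CCN"), list("GGGG"), STRICT)
        assert res.status is ColumnStatus.CANDIDATE
        assert res.missing_count == 1

    def test_derived_state_in_outgroup_rejected_in_strict_mode(self):
        params = ScanParams(outgroup_majority_threshold=0.75,
                            forbid_derived_in_outgroup=True)
        res = classify_column(list("CCN"), list("GGGC"), params)
        assert res.status is ColumnStatus.REJECTED
        relaxed = ScanParams(outgroup_majority_threshold=0.75,
                             forbid_derived_in_outgroup=False)
        res2 = classify_column(list("CCN"), list("GGGC"), relaxed)
        assert res2.status is ColumnStatus.CANDIDATE

    def test_focal_variation_rejected(self):
        res = classify_column(list("CTC"), list("GGGG"), STRICT)
        assert res.status is ColumnStatus.REJECTED

    def test_focal_equal_to_outgroup_majority_rejected(self):
        res = classify_column(list("GGG"), list("GGGG"), STRICT)
        assert res.status is ColumnStatus.REJECTED

    def test_all_missing_is_uninformative_not_rejected(self):
        res = classify_column(list("NNN"), list("GGGG"), STRICT)
        assert res.status is ColumnStatus.UNINFORMATIVE
        res = classify_column(list("CCC"), list("NN--"), STRICT)
        assert res.status is ColumnStatus.UNINFORMATIVE

    def test_state_only_when_outgroup_has_no_majority(self):
        # outgroup evenly split, focal state absent from it: ancestor unclear
        res = classify_column(list("CCC"), list("GGTT"), ScanParams())
        assert res.status is ColumnStatus.CANDIDATE
        assert res.kind == KIND_STATE_ONLY and res.ancestral is None
        # focal state present in the split outgroup: no character
        res = classify_column(list("CCC"), list("GGCC"), ScanParams())
        assert res.status is ColumnStatus.REJECTED

    def test_ambiguity_codes_count_as_missing(self):
        res = classify_column(list("CCR"), list("GGGG"), STRICT)
        assert res.status is ColumnStatus.CANDIDATE
        assert res.missing_count == 1


class TestRanking:
    def _aln(self, coverage):
        taxa = ["f1", "f2", "o1", "o2"]
        # two diagnostic columns: col 1 has a missing focal taxon, col 3 none
        rows = ["CACTA", "NACTA", "GAATA", "GAATA"]
        return make_alignment(
            taxa, {"aly1.1.1": {"rows": rows}},
            coverage={LocusRef.parse("aly1.1.1"): coverage} if coverage else None,
        )

    def test_missing_count_dominates_coverage(self):
        cov = [[9, 9, 9, 9, 9], [99, 99, 99, 99, 99], [9] * 5, [9] * 5]
        aln = self._aln(cov)
        clades = CladePartition(focal=frozenset({"f1", "f2"}),
                                outgroups=frozenset({"o1", "o2"}))
        chars = scan_clade(aln, clades, STRICT)
        assert [(c.position, c.missing_count) for c in chars] == [(3, 0), (1, 1)]

    def test_coverage_breaks_ties(self):
        taxa = ["f1", "f2", "o1", "o2"]
        rows = ["CACAA", "CACAA", "GAGAA", "GAGAA"]  # diagnostic at cols 1 and 3
        cov = [[12, 1, 30, 1, 1], [12, 1, 30, 1, 1], [5] * 5, [5] * 5]
        aln = make_alignment(
            taxa, {"aly1.1.1": {"rows": rows}},
            coverage={LocusRef.parse("aly1.1.1"): cov},
        )
        clades = CladePartition(focal=frozenset({"f1", "f2"}),
                                outgroups=frozenset({"o1", "o2"}))
        chars = scan_clade(aln, clades, STRICT)
        assert [c.position for c in chars] == [3, 1]
        assert [c.min_coverage for c in chars] == [30, 12]

    def test_top_k_truncation(self, four_vs_outgroup):
        aln, clades = four_vs_outgroup
        assert len(scan_clade(aln, clades, ScanParams(top_k=1))) == 1


class TestSingleton:
    def _fixture(self):
        # taxa: focal singleton F; sister clade s1,s2; parent outgroup p1,p2;
        # distant outgroups o1,o2.
        taxa = ["F", "s1", "s2", "p1", "p2", "o1", "o2"]
        rows = [
            # col1: sister synapomorphy A->C, F retains A  -> "A1A (not C)"
            # col2: F and the parent outgroup share the sister state -> nothing
            # col3: F missing at a sister synapomorphy; parent outgroup
            #       polymorphic, so neither route reports it
            # col4: synapomorphy of F+sister vs parent outgroup (T->G)
            # col5: constant
            "ACNGT",  # F
            "CCGGT",  # s1
            "CCGGT",  # s2
            "ACGTT",  # p1
            "ACTTT",  # p2
            "AATTT",  # o1
            "AATTT",  # o2
        ]
        aln = make_alignment(taxa, {"aly1.1.1": {"rows": rows}})
        clades = CladePartition(
            focal=frozenset({"F"}),
            sister=frozenset({"s1", "s2"}),
            parent_outgroup=frozenset({"p1", "p2"}),
            outgroups=frozenset({"o1", "o2"}),
        )
        return aln, clades

    def test_union_of_retained_and_parent_characters(self):
        aln, clades = self._fixture()
        chars = scan_singleton(aln, clades, STRICT)
        rendered = {render(c) for c in chars}
        assert "aly1.1.1:A1A (not C)" in rendered
        assert "aly1.1.1:T4G" in rendered
        positions = {c.position for c in chars}
        assert 2 not in positions  # focal shares the sister state
        assert 3 not in positions  # focal missing at the sister synapomorphy

    def test_requires_singleton_and_sister(self):
        aln, clades = self._fixture()
        with pytest.raises(ValueError):
            scan_singleton(aln, CladePartition(
                focal=frozenset({"F", "s1"}), outgroups=clades.outgroups,
                sister=frozenset({"s2"}), parent_outgroup=clades.parent_outgroup,
            ), STRICT)
        with pytest.raises(ValueError):
            scan_singleton(aln, CladePartition(
                focal=frozenset({"F"}), outgroups=clades.outgroups,
            ), STRICT)


class TestBarcode:
    def _barcode_aln(self):
        taxa = ["f1", "f2", "o1", "o2"]
        base = ["A"] * 658
        rows = []
        for taxon in taxa:
            seq = base.copy()
            if taxon.startswith("f"):
                seq[234] = "T"  # barcode position 235
            else:
                seq[234] = "C"
            rows.append("".join(seq))
        return make_alignment(
            taxa, {LocusRef("coi", 1, 1, 1): {"rows": rows, "partition": "coi_barcode"}}
        )

    def test_barcode_character_rendered_in_barcode_dialect(self):
        aln = self._barcode_aln()
        clades = CladePartition(focal=frozenset({"f1", "f2"}),
                                outgroups=frozenset({"o1", "o2"}))
        chars = scan_barcode(aln, clades, STRICT)
        assert [render(c) for c in chars] == ["C235T"]
        assert chars[0].locus is None and chars[0].position == 235

    def test_no_differences_yields_empty_list(self):
        taxa = ["f1", "f2", "o1"]
        rows = ["A" * 658] * 3
        aln = make_alignment(
            taxa, {LocusRef("coi", 1, 1, 1): {"rows": rows, "partition": "coi_barcode"}}
        )
        clades = CladePartition(focal=frozenset({"f1", "f2"}),
                                outgroups=frozenset({"o1"}))
        assert scan_barcode(aln, clades, STRICT) == []


def _random_case(rng):
    n_taxa = int(rng.integers(4, 9))
    n_cols = int(rng.integers(5, 51))
    taxa = [f"t{i}" for i in range(n_taxa)]
    alphabet = np.array(list("ACGTACGTACGTN-R"))  # missing/ambiguity at ~20%
    rows = ["".join(rng.choice(alphabet, size=n_cols)) for _ in range(n_taxa)]
    k = int(rng.integers(1, n_taxa))
    focal = frozenset(taxa[:k])
    outgroups = frozenset(taxa[k:])
    threshold = float(rng.choice([0.6, 0.75, 0.9, 1.0]))
    forbid = bool(rng.integers(2))
    return taxa, rows, focal, outgroups, threshold, forbid


def _identity_list(chars):
    return [
        (str(c.locus), c.position, c.kind, c.ancestral, c.derived, c.missing_count)
        for c in chars
    ]


@pytest.mark.parametrize("seed", [0, 1])
def test_scan_clade_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    for _ in range(50):
        taxa, rows, focal, outgroups, threshold, forbid = _random_case(rng)
        aln = make_alignment(taxa, {"aly1.1.1": {"rows": rows}})
        params = ScanParams(
            outgroup_majority_threshold=threshold,
            forbid_derived_in_outgroup=forbid,
            top_k=10_000,
        )
        got = _identity_list(scan_clade(aln, params=params, clades=CladePartition(
            focal=focal, outgroups=outgroups)))
        expected = [
            ("aly1.1.1", h["position"], h["kind"], h["ancestral"], h["derived"],
             h["missing"])
            for h in brute_force_scan(
                [("aly1.1.1", rows)], taxa, focal, outgroups, threshold, forbid,
                max_missing=len(focal) - 1,
            )
        ]
        assert got == expected


@pytest.mark.parametrize("seed", [7])
def test_reported_positions_monotone_in_params(seed):
    """Raising max_focal_missing or lowering the outgroup majority threshold
    never removes a reported position (pre-truncation)."""
    rng = np.random.default_rng(seed)
    for _ in range(25):
        taxa, rows, focal, outgroups, _, _ = _random_case(rng)
        aln = make_alignment(taxa, {"aly1.1.1": {"rows": rows}})
        clades = CladePartition(focal=focal, outgroups=outgroups)

        def positions(threshold, max_missing):
            params = ScanParams(outgroup_majority_threshold=threshold,
                                forbid_derived_in_outgroup=True,
                                max_focal_missing=max_missing, top_k=10_000)
            return {c.position for c in scan_clade(aln, clades, params)}

        assert positions(0.9, 0) <= positions(0.9, len(focal))
        assert positions(1.0, len(focal)) <= positions(0.75, len(focal))


def test_rank_order_is_deterministic(four_vs_outgroup):
    aln, clades = four_vs_outgroup
    a = scan_clade(aln, clades, STRICT)
    b = scan_clade(aln, clades, STRICT)
    assert _identity_list(a) == _identity_list(b)


def test_audit_table_covers_every_column(four_vs_outgroup):
    aln, clades = four_vs_outgroup
    table = audit_table(aln, clades, STRICT)
    assert len(table) == 5
    assert set(table.status) <= {"candidate", "rejected", "uninformative"}
    assert (table[table.position == 1].status == "candidate").all()
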