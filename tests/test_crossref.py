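"""Reference construction, lexical matching, matrix build and comparison."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from enzpam.annotation import AnnotationRecord
from enzpam.crossref import (
    PresenceAbsenceMatrix,
    build_matrix,
    build_reference,
    compare_matrices,
    match_annotations,
    read_reference,
    write_reference,
)
from enzpam.errors import MatrixError, ReferenceError_
from enzpam.harvest import SynonymRecord, normalize_name
from tests.conftest import make_spec


def syn(enzyme_id, name, source="kegg_snapshot", via="ko"):
    return SynonymRecord(
        enzyme_id=enzyme_id, raw_name=name, norm_name=normalize_name(name),
        source=source, retrieved_via=via,
    )


def cds(genome, locus, product):
    return AnnotationRecord(
        genome_id=genome, locus_tag=locus, feature_type="CDS",
        ec_text="", gene="", product=product,
    )


@pytest.fixture
def two_enzymes():
    a = make_spec("catechol 1,2-dioxygenase", "catechol degradation")
    b = make_spec("benzoate 1,2-dioxygenase", "benzene degradation", ecs=("1.14.12.10",), kos=())
    return a, b


class TestBuildReference:
    def test_disjoint_synonyms_no_collisions(self, two_enzymes):
        a, b = two_enzymes
        syns = [
            syn(a.enzyme_id, n) for n in ("catechol 1,2-dioxygenase", "catA", "pyrocatechase")
        ] + [syn(b.enzyme_id, n) for n in ("benzoate 1,2-dioxygenase", "benA", "benzoate oxygenase")]
        entries, collisions = build_reference([a, b], syns)
        assert len(entries) == 6
        assert collisions == {}
        assert {e.standard_name for e in entries} == {a.standard_name, b.standard_name}

    def test_shared_synonym_reported_once(self, two_enzymes):
        a, b = two_enzymes
        syns = [syn(a.enzyme_id, "dioxygenase"), syn(b.enzyme_id, "dioxygenase")]
        entries, collisions = build_reference([a, b], syns)
        assert len(entries) == 2
        assert collisions == {"dioxygenase": sorted([a.enzyme_id, b.enzyme_id])}

    def test_dangling_enzyme_id_errors(self, two_enzymes):
        a, _ = two_enzymes
        with pytest.raises(ReferenceError_, match="ghost"):
            build_reference([a], [syn("ghost__enzyme", "name")])

    def test_identifier_fields_joined(self, two_enzymes):
        a, _ = two_enzymes
        entries, _ = build_reference([a], [syn(a.enzyme_id, a.standard_name)])
        (e,) = entries
        assert e.ec_numbers == "1.13.11.1" and e.ko_ids == "K03381"

    def test_tsv_roundtrip_with_collision_section(self, two_enzymes, tmp_path):
        a, b = two_enzymes
        syns = [syn(a.enzyme_id, "dioxygenase"), syn(b.enzyme_id, "dioxygenase")]
        entries, collisions = build_reference([a, b], syns)
        p = tmp_path / "ref.tsv"
        write_reference(entries, p, collisions)
        assert read_reference(p) == entries


class TestMatchAnnotations:
    @pytest.fixture
    def reference(self, two_enzymes):
        a, b = two_enzymes
        entries, _ = build_reference(
            [a, b],
            [syn(a.enzyme_id, "catechol 1,2-dioxygenase"), syn(b.enzyme_id, "benzoate 1,2-dioxygenase")],
        )
        return entries

    def test_exact_equality_matches(self, reference):
        (m,) = match_annotations([cds("g1", "L1", "catechol 1,2-dioxygenase")], reference)
        assert not m.excluded and m.match_mode == "exact"

    def test_decorated_product_needs_substring_mode(self, reference):
        rec = [cds("g1", "L1", "putative catechol 1,2-dioxygenase protein")]
        assert match_annotations(rec, reference, mode="exact") == []
        (m,) = match_annotations(rec, reference, mode="substring")
        assert m.matched_norm_name == "catechol 1,2-dioxygenase"

    def test_word_boundary_blocks_partial_words(self, two_enzymes):
        a, _ = two_enzymes
        entries, _ = build_reference([a], [syn(a.enzyme_id, "oxygenase")])
        rec = [cds("g1", "L1", "catechol 1,2-dioxygenase")]
        assert match_annotations(rec, entries, mode="substring") == []

    def test_curation_excludes_whole_product_line(self, reference, tmp_path):
        cur = tmp_path / "curation.txt"
        cur.write_text("# unwanted\nputative catechol 1,2-dioxygenase protein\n")
        rec = [cds("g1", "L1", "putative catechol 1,2-dioxygenase protein")]
        (m,) = match_annotations(rec, reference, mode="substring", curation_path=cur)
        assert m.excluded and "curated out" in m.exclusion_reason

    def test_curation_excludes_by_synonym(self, reference, tmp_path):
        cur = tmp_path / "curation.txt"
        cur.write_text("catechol 1,2-dioxygenase\n")
        (m,) = match_annotations(
            [cds("g1", "L1", "Catechol 1,2-Dioxygenase")], reference, curation_path=cur
        )
        assert m.excluded

    def test_ambiguous_synonym_scores_all_owners(self, two_enzymes):
        a, b = two_enzymes
        entries, _ = build_reference(
            [a, b], [syn(a.enzyme_id, "dioxygenase"), syn(b.enzyme_id, "dioxygenase")]
        )
        ms = match_annotations([cds("g1", "L1", "dioxygenase")], entries)
        assert {m.enzyme_id for m in ms} == {a.enzyme_id, b.enzyme_id}
        assert all(m.ambiguous for m in ms)

    def test_non_cds_records_never_match(self, reference):
        rec = AnnotationRecord(
            genome_id="g1", locus_tag="T1", feature_type="other",
            ec_text="", gene="", product="catechol 1,2-dioxygenase",
        )
        assert match_annotations([rec], reference) == []

    def test_exact_positives_subset_of_substring(self, reference):
        recs = [
            cds("g1", f"L{i}", p)
            for i, p in enumerate(
                [
                    "catechol 1,2-dioxygenase",
                    "putative benzoate 1,2-dioxygenase",
                    "unrelated protein",
                ]
            )
        ]
        exact = {(m.enzyme_id, m.genome_id) for m in match_annotations(recs, reference, "exact")}
        sub = {(m.enzyme_id, m.genome_id) for m in match_annotations(recs, reference, "substring")}
        assert exact <= sub


class TestBuildMatrix:
    def test_all_zero_when_no_matches(self, two_enzymes):
        a, b = two_enzymes
        m = build_matrix([], [a, b], ["g1", "g2"])
        assert all(v == 0 for v in m.cells.values())
        assert m.enzyme_ids == [a.enzyme_id, b.enzyme_id]
        assert m.genome_ids == ["g1", "g2"]

    def test_two_matches_one_cell_two_locus_tags(self, two_enzymes):
        a, b = two_enzymes
        entries, _ = build_reference([a], [syn(a.enzyme_id, a.standard_name)])
        recs = [cds("g1", "L1", a.standard_name), cds("g1", "L2", a.standard_name)]
        matches = match_annotations(recs, entries)
        m = build_matrix(matches, [a], ["g1"])
        assert m.value(a.enzyme_id, "g1") == 1
        assert m.provenance[(a.enzyme_id, "g1")] == ["L1", "L2"]

    def test_excluded_matches_do_not_contribute(self, two_enzymes, tmp_path):
        a, _ = two_enzymes
        entries, _ = build_reference([a], [syn(a.enzyme_id, a.standard_name)])
        cur = tmp_path / "c.txt"
        cur.write_text(a.standard_name + "\n")
        matches = match_annotations([cds("g1", "L1", a.standard_name)], entries, curation_path=cur)
        m = build_matrix(matches, [a], ["g1"])
        assert m.value(a.enzyme_id, "g1") == 0

    def test_unknown_genome_errors(self, two_enzymes):
        a, _ = two_enzymes
        entries, _ = build_reference([a], [syn(a.enzyme_id, a.standard_name)])
        matches = match_annotations([cds("gX", "L1", a.standard_name)], entries)
        with pytest.raises(MatrixError, match="gX"):
            build_matrix(matches, [a], ["g1"])

    def test_matrix_tsv_roundtrip(self, small_bundle, tmp_path):
        p = tmp_path / "m.tsv"
        q = tmp_path / "prov.tsv"
        small_bundle.truth.write(p, q)
        back = PresenceAbsenceMatrix.read(p, q)
        assert back.cells == small_bundle.truth.cells
        assert back.provenance == small_bundle.truth.provenance


def random_matrix(rng, enzyme_ids, genome_ids):
    cells = {(e, g): rng.randint(0, 1) for e in enzyme_ids for g in genome_ids}
    return PresenceAbsenceMatrix(
        enzyme_ids=list(enzyme_ids),
        genome_ids=list(genome_ids),
        cells=cells,
        provenance={},
        pathways={e: "pw" for e in enzyme_ids},
        standard_names={e: e for e in enzyme_ids},
    )


class TestCompareMatrices:
    def test_identical_matrices(self, small_bundle):
        cmp = compare_matrices(small_bundle.truth, small_bundle.truth)
        n = len(small_bundle.truth.positives())
        assert cmp.n_pos_a == cmp.n_pos_b == cmp.n_shared == n
        assert cmp.n_only_a == cmp.n_only_b == 0
        assert cmp.frac_of_b_reproduced == 1.0

    def test_all_zero_against_positives(self):
        rng = random.Random(1)
        b = random_matrix(rng, ["e1", "e2", "e3"], ["g1", "g2"])
        a = random_matrix(rng, ["e1", "e2", "e3"], ["g1", "g2"])
        a.cells = {k: 0 for k in a.cells}
        cmp = compare_matrices(a, b)
        assert cmp.frac_of_b_reproduced == (0.0 if b.positives() else None)
        assert cmp.frac_only_a is None

    def test_hand_computed_partition(self):
        enzyme_ids, genome_ids = ["e1", "e2", "e3"], ["g1", "g2"]
        a = random_matrix(random.Random(0), enzyme_ids, genome_ids)
        b = random_matrix(random.Random(0), enzyme_ids, genome_ids)
        a.cells = {k: 0 for k in a.cells}
        b.cells = {k: 0 for k in b.cells}
        a.cells[("e1", "g1")] = a.cells[("e2", "g1")] = 1
        b.cells[("e1", "g1")] = b.cells[("e3", "g2")] = 1
        cmp = compare_matrices(a, b)
        assert (cmp.n_shared, cmp.n_only_a, cmp.n_only_b) == (1, 1, 1)
        assert cmp.frac_of_b_reproduced == 0.5

    def test_label_mismatch_lists_difference(self):
        a = random_matrix(random.Random(0), ["e1"], ["g1"])
        b = random_matrix(random.Random(0), ["e2"], ["g1"])
        with pytest.raises(MatrixError, match="e1"):
            compare_matrices(a, b)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_conservation_identities_vs_brute_force(self, seed):
        rng = random.Random(seed)
        enzyme_ids = [f"e{i}" for i in range(rng.randint(1, 6))]
        genome_ids = [f"g{i}" for i in range(rng.randint(1, 5))]
        a = random_matrix(rng, enzyme_ids, genome_ids)
        b = random_matrix(rng, enzyme_ids, genome_ids)
        cmp = compare_matrices(a, b)
        pos_a = {k for k, v in a.cells.items() if v}
        pos_b = {k for k, v in b.cells.items() if v}
        assert cmp.n_shared == len(pos_a & pos_b)
        assert cmp.n_only_a == len(pos_a - pos_b)
        assert cmp.n_only_b == len(pos_b - pos_a)
        assert cmp.n_shared + cmp.n_only_a == cmp.n_pos_a
        assert cmp.n_shared + cmp.n_only_b == cmp.n_pos_b
        for frac in (cmp.frac_of_b_reproduced, cmp.frac_only_a):
            assert frac is None or 0.0 <= frac <= 1.0
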