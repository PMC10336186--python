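"""Custom-database construction and the FASTA header convention."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from enzpam.dbbuild import (
    AA_ALPHABET,
    CustomDbEntry,
    build_custom_db,
    parse_custom_db,
    retrieve_sequences,
    write_pathway_dbs,
)
from enzpam.errors import DbFormatError
from enzpam.harvest import SnapshotSource, SynonymRecord, normalize_name
from tests.conftest import make_spec


def entry(seq_id="SDB_000001", ec="1.13.11.1", gene="catA",
          product="catechol 1,2-dioxygenase", enzyme_id="pw__e", seq="MKT" * 30):
    return CustomDbEntry(
        seq_id=seq_id, ec_text=ec, gene=gene, product=product,
        enzyme_id=enzyme_id, sequence=seq,
    )


class TestCustomDbEntry:
    def test_rejects_delimiter_in_fields(self):
        with pytest.raises(DbFormatError, match="~~~"):
            entry(product="bad~~~name")

    def test_rejects_bad_residues(self):
        with pytest.raises(DbFormatError):
            entry(seq="MKTZ")

    def test_rejects_empty_product(self):
        with pytest.raises(DbFormatError):
            entry(product="")


class TestBuildCustomDb:
    def test_header_convention(self, tmp_path):
        out = tmp_path / "db.faa"
        build_custom_db([entry()], out)
        first = out.read_text().splitlines()[0]
        assert first == ">SDB_000001 1.13.11.1~~~catA~~~catechol 1,2-dioxygenase"

    def test_empty_gene_leaves_adjacent_delimiters(self, tmp_path):
        out = tmp_path / "db.faa"
        build_custom_db([entry(gene="")], out)
        assert "1.13.11.1~~~~~~catechol 1,2-dioxygenase" in out.read_text().splitlines()[0]

    def test_sixty_column_wrapping(self, tmp_path):
        out = tmp_path / "db.faa"
        build_custom_db([entry(seq="M" * 150)], out)
        lines = out.read_text().splitlines()[1:]
        assert [len(l) for l in lines] == [60, 60, 30]

    def test_empty_collection_gives_empty_fasta_and_zero_counts(self, tmp_path):
        spec = make_spec("enzyme a", "pw")
        out = tmp_path / "db.faa"
        manifest = build_custom_db([], out, [spec])
        assert out.read_text() == ""
        assert manifest["n_entries"] == 0
        assert manifest["per_pathway"] == {"pw": 0}

    def test_duplicate_seq_ids_rejected(self, tmp_path):
        with pytest.raises(DbFormatError, match="SDB_000001"):
            build_custom_db([entry(), entry()], tmp_path / "db.faa")

    def test_manifest_pathway_counts_sum_to_total(self, tmp_path):
        specs = [make_spec("enzyme a", "pw1"), make_spec("enzyme b", "pw2")]
        entries = [
            entry(seq_id=f"S{i}", enzyme_id=specs[i % 2].enzyme_id) for i in range(7)
        ]
        manifest = build_custom_db(entries, tmp_path / "db.faa", specs)
        assert sum(manifest["per_pathway"].values()) == manifest["n_entries"] == 7

    def test_byte_identical_across_runs(self, tmp_path):
        entries = [entry(seq_id=f"S{i}") for i in range(5)]
        a, b = tmp_path / "a.faa", tmp_path / "b.faa"
        build_custom_db(entries, a)
        build_custom_db(entries, b)
        assert a.read_bytes() == b.read_bytes()


class TestParseCustomDb:
    def test_roundtrip_fields(self, tmp_path):
        rng = random.Random(3)
        alphabet = sorted(AA_ALPHABET)
        entries = [
            entry(
                seq_id=f"S{i:03d}",
                ec="" if i % 3 == 0 else "1.1.1.1",
                gene="" if i % 2 == 0 else f"gen{i}",
                product=f"protein number {i}",
                seq="".join(rng.choices(alphabet, k=rng.randint(1, 200))),
            )
            for i in range(10)
        ]
        out = tmp_path / "db.faa"
        build_custom_db(entries, out)
        parsed = parse_custom_db(out)
        for orig, back in zip(entries, parsed):
            for f in ("seq_id", "ec_text", "gene", "product", "sequence"):
                assert getattr(orig, f) == getattr(back, f)

    def test_enzyme_id_recovered_via_synonym_lookup(self, tmp_path):
        syn = SynonymRecord(
            enzyme_id="pw__e",
            raw_name="catechol 1,2-dioxygenase",
            norm_name="catechol 1,2-dioxygenase",
            source="manual",
            retrieved_via="manual",
        )
        out = tmp_path / "db.faa"
        build_custom_db([entry()], out)
        (parsed,) = parse_custom_db(out, [syn])
        assert parsed.enzyme_id == "pw__e"

    def test_malformed_header_names_line(self, tmp_path):
        p = tmp_path / "bad.faa"
        p.write_text(">S1 no delimiters here\nMKT\n")
        with pytest.raises(DbFormatError, match="bad.faa:1"):
            parse_custom_db(p)

    def test_handwritten_single_entry(self, tmp_path):
        p = tmp_path / "one.faa"
        p.write_text(">ACC9 2.7.1.40~~~pykA~~~pyruvate kinase\nMKTAYIAKQR\n")
        (e,) = parse_custom_db(p)
        assert (e.seq_id, e.ec_text, e.gene, e.product, e.sequence) == (
            "ACC9", "2.7.1.40", "pykA", "pyruvate kinase", "MKTAYIAKQR",
        )


class TestRetrieveSequences:
    @pytest.fixture
    def source(self, tmp_path):
        d = tmp_path / "snap"
        d.mkdir()
        (d / "proteins.fasta").write_text(
            ">ACC1 catechol 1,2-dioxygenase\nMKTA\n"
            ">ACC2 catechol 1,2-dioxygenase\nMKTC\n"
            ">ACC3 catechol 1,2-dioxygenase\nMKTD\n"
            ">ACC4 unrelated protein\nMKTE\n"
        )
        return SnapshotSource(d)

    @pytest.fixture
    def syn(self):
        return SynonymRecord(
            enzyme_id="catechol-degradation__catechol-1-2-dioxygenase",
            raw_name="catechol 1,2-dioxygenase",
            norm_name="catechol 1,2-dioxygenase",
            source="kegg_snapshot",
            retrieved_via="ko",
        )

    def test_multiple_hits_share_product(self, source, syn):
        spec = make_spec("catechol 1,2-dioxygenase", "catechol degradation")
        entries, misses = retrieve_sequences([syn], source, [spec])
        assert len(entries) == 3 and not misses
        assert {e.product for e in entries} == {"catechol 1,2-dioxygenase"}
        assert {e.ec_text for e in entries} == {"1.13.11.1"}

    def test_zero_hits_go_to_miss_report(self, source):
        syn = SynonymRecord(
            enzyme_id="pw__x", raw_name="nothing here",
            norm_name="nothing here", source="manual", retrieved_via="manual",
        )
        entries, misses = retrieve_sequences([syn], source, [make_spec("nothing here", "pw")])
        assert entries == [] and len(misses) == 1

    def test_cap_takes_first_by_snapshot_order(self, source, syn):
        spec = make_spec("catechol 1,2-dioxygenase", "catechol degradation")
        entries, _ = retrieve_sequences([syn], source, [spec], max_seqs_per_synonym=1)
        assert [e.seq_id for e in entries] == ["ACC1"]


def test_per_pathway_dbs_partition_the_merged_db(tmp_path):
    specs = [make_spec("enzyme a", "pw1"), make_spec("enzyme b", "pw2")]
    entries = [entry(seq_id=f"S{i}", enzyme_id=specs[i % 2].enzyme_id) for i in range(6)]
    paths = write_pathway_dbs(entries, specs, tmp_path)
    merged = parse_custom_db(paths["__merged__"])
    split = [e for pw in ("pw1", "pw2") for e in parse_custom_db(paths[pw])]
    assert {e.seq_id for e in merged} == {e.seq_id for e in split}
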