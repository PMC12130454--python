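import gzip
import io
import random
import tarfile
import zipfile
from collections import Counter

import pytest

from treeharvest.simulate import random_newick
from treeharvest.treescan import (
    FileEntry,
    TREE_SUFFIXES,
    candidate_from_tree,
    discover_tree_files,
    has_tree_suffix,
    normalize_tip_label,
    validate_tree_file,
)

NEXUS_TRANSLATE = """#NEXUS
BEGIN TREES;
    TRANSLATE
        1 Homo_sapiens,
        2 Pan_troglodytes;
    TREE t1 = (1,2);
END;
"""


def zip_bytes(members: dict[str, bytes]) -> bytes:
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w") as zf:
        for name, data in members.items():
            zf.writestr(name, data)
    return buf.getvalue()


class TestDiscover:
    def test_suffix_whitelist_ignores_case(self):
        entries = [
            FileEntry("tree.NWK", b"(A,B);"),
            FileEntry("aln.fasta", b">a\nACGT\n"),
        ]
        found = discover_tree_files(entries)
        assert [e.name for e in found] == ["tree.NWK"]

    def test_zip_archive_expanded_and_filtered(self):
        data = zip_bytes({"x.tre": b"(A,B);", "y.csv": b"a,b\n"})
        found = discover_tree_files([FileEntry("data.zip", data)])
        assert [e.name for e in found] == ["x.tre"]
        assert found[0].origin == "data.zip/x.tre"

    def test_tar_and_gz_archives(self):
        buf = io.BytesIO()
        with tarfile.open(fileobj=buf, mode="w") as tf:
            payload = b"(A,B,C);"
            info = tarfile.TarInfo("inner/t.tree")
            info.size = len(payload)
            tf.addfile(info, io.BytesIO(payload))
        found = discover_tree_files([FileEntry("arch.tar", buf.getvalue())])
        assert [e.name for e in found] == ["t.tree"]

        gz = gzip.compress(b"(A,B);")
        found = discover_tree_files([FileEntry("t.nwk.gz", gz)])
        assert [e.name for e in found] == ["t.nwk"]

    def test_nested_archives_expand_to_depth_limit(self):
        inner = zip_bytes({"deep.tre": b"(A,B);"})
        mid = zip_bytes({"mid.zip": inner})
        outer = zip_bytes({"outer.zip": mid})
        assert [e.name for e in discover_tree_files([FileEntry("top.zip", outer)])] == [
            "deep.tre"
        ]
        # one level deeper exceeds the depth limit: subtree skipped, no crash
        deeper = zip_bytes({"deeper.zip": outer})
        assert discover_tree_files([FileEntry("top4.zip", deeper)]) == []

    def test_corrupt_archive_skipped_with_warning(self, caplog):
        found = discover_tree_files([FileEntry("bad.zip", b"not a zip at all")])
        assert found == []

    def test_brute_force_suffix_oracle_on_mixed_fixture(self):
        rng = random.Random(42)
        suffixes = sorted(TREE_SUFFIXES) + [".fasta", ".csv", ".json", ".xml"]
        entries = [
            FileEntry(f"file{i}{rng.choice(suffixes)}", b"") for i in range(50)
        ]
        expected = [e.name for e in entries if e.name.rsplit(".", 1)[-1].lower() in
                    {s[1:] for s in TREE_SUFFIXES}]
        assert [e.name for e in discover_tree_files(entries)] == expected


class TestValidate:
    def test_simple_newick(self):
        rec = validate_tree_file(b"(A,B,(C,D));", "t.nwk")
        assert rec.valid and rec.format == "newick"
        assert rec.tree_count == 1
        assert rec.tip_labels == Counter({"A": 1, "B": 1, "C": 1, "D": 1})

    def test_plain_text_is_invalid(self):
        rec = validate_tree_file(b"hello world", "notes.txt")
        assert not rec.valid and rec.reason == "parse"

    def test_nexus_translate_resolved(self):
        # independent hand parse: TRANSLATE maps 1->Homo_sapiens, 2->Pan_troglodytes
        rec = validate_tree_file(NEXUS_TRANSLATE.encode(), "t.nex")
        assert rec.valid and rec.format == "nexus"
        assert set(rec.tip_labels) == {"Homo_sapiens", "Pan_troglodytes"}

    def test_duplicate_tip_labels_counted_as_multiset(self):
        rec = validate_tree_file(b"((A,B),(A,C));", "t.nwk")
        assert rec.valid
        assert rec.tip_labels == Counter({"A": 2, "B": 1, "C": 1})

    def test_single_tip_tree_is_degenerate(self):
        rec = validate_tree_file(b"(A);", "t.nwk")
        assert not rec.valid and rec.reason == "degenerate"

    def test_undecodable_bytes_fall_back_to_latin1(self):
        rec = validate_tree_file("(Ané,Bé);".encode("latin-1"), "t.nwk")
        assert rec.valid and rec.tip_count == 2

    def test_multi_tree_file_counts(self):
        rec = validate_tree_file(b"(A,B);\n(C,(D,E));\n", "t.tre")
        assert rec.tree_count == 2
        assert rec.tip_count == 5


class TestNormalizeTipLabel:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Homo_sapiens_AB123", ["Homo sapiens", "Homo"]),
            ("'Leptotila verreauxi'", ["Leptotila verreauxi", "Leptotila"]),
            ("Mya|arenaria|12345", ["Mya arenaria", "Mya"]),
            ("Columba", ["Columba"]),
            ("12345", []),
        ],
    )
    def test_candidate_emission(self, raw, expected):
        assert normalize_tip_label(raw) == expected

    def test_generated_labels_recover_their_binomials(self):
        rng = random.Random(9)
        for i in range(100):
            genus = "Gen" + str(i)
            epithet = "sp" + "".join(rng.choice("abcdef") for _ in range(5))
            raw = f"{genus}_{epithet}_{rng.randrange(10**6)}"
            assert f"{genus} {epithet}" in normalize_tip_label(raw)


class TestCandidateFromTree:
    def test_leptotila_under_assignment_failure_mode(self, toy_index):
        # a class-wide bird study whose tips are dominated by one genus gets
        # that genus as Name2 even though the true scope (Aves) is broader
        rec = validate_tree_file(
            b"((Leptotila_verreauxi,Leptotila_sp1),(Columba_livia,Unknown_bird));",
            "aves.nwk",
        )
        cand = candidate_from_tree([rec], toy_index)
        assert (cand.name, cand.rank, cand.method) == ("Leptotila", "genus", "tree")

    def test_empty_records_absent(self, toy_index):
        assert candidate_from_tree([], toy_index) is None

    def test_brute_force_counting_oracle(self, toy_index):
        rec = validate_tree_file(
            b"((Homo_sapiens,Homo_neanderthalensis),Pan_troglodytes);", "t.nwk"
        )
        cand = candidate_from_tree([rec], toy_index)
        assert (cand.name, cand.frequency) == ("Homo", 2)
        assert ("Pan", "genus", 1) in cand.alternatives

    def test_species_matches_propagate_to_genus(self, toy_index):
        rec = validate_tree_file(b"(Homo_sapiens,Pan_troglodytes);", "t.nwk")
        cand = candidate_from_tree([rec], toy_index)
        # species + genus tie at freq 1 each; broader rank (genus) wins; the
        # credibility floor passes because 1 match >= 10% of 2 pooled tips
        assert cand.rank == "genus"

    def test_credibility_floor_rejects_single_weak_match(self, toy_index):
        tips = ",".join([f"x{i}" for i in range(19)] + ["Leptotila_verreauxi"])
        rec = validate_tree_file(f"({tips});".encode(), "t.nwk")
        assert candidate_from_tree([rec], toy_index) is None
        # the floor is tunable
        cand = candidate_from_tree([rec], toy_index, min_count=1, min_fraction=0.0)
        assert cand is not None

    def test_pooling_across_files(self, toy_index):
        recs = [
            validate_tree_file(b"(Leptotila_verreauxi,x1);", "a.nwk"),
            validate_tree_file(b"(Leptotila_sp2,x2);", "b.nwk"),
        ]
        cand = candidate_from_tree(recs, toy_index)
        assert cand.name == "Leptotila" and cand.frequency == 2


class TestRoundTrip:
    def test_serialize_reparse_preserves_leaf_multisets(self):
        rng = random.Random(7)
        for _ in range(200):
            n = rng.randint(2, 20)
            labels = [f"T{rng.randrange(n)}" for _ in range(n)]  # duplicates allowed
            newick = random_newick(labels, rng)
            rec = validate_tree_file(newick.encode(), "r.nwk")
            assert rec.valid
            again = validate_tree_file(rec.newick.encode(), "r2.nwk")
            assert again.valid
            assert again.tip_labels == rec.tip_labels == Counter(labels)

    def test_tip_count_matches_comma_oracle(self):
        # any single-tree Newick without quoted commas has leaves = commas + 1
        rng = random.Random(8)
        for _ in range(100):
            labels = [f"L{i}" for i in range(rng.randint(2, 15))]
            newick = random_newick(labels, rng)
            rec = validate_tree_file(newick.encode(), "o.nwk")
            assert rec.tip_count == newick.count(",") + 1


def test_has_tree_suffix_exactness():
    for s in TREE_SUFFIXES:
        assert has_tree_suffix(f"file{s}")
        assert has_tree_suffix(f"FILE{s.upper()}")
    for bad in [".fa", ".nw", ".nexml", ".treez", ".xml", ""]:
        assert not has_tree_suffix(f"file{bad}")
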