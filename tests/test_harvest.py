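import random

import pytest

from treeharvest.harvest import (
    CROSSREF_WORKS_URL,
    DRYAD_SEARCH_URL,
    EdgeListTree,
    FIGSHARE_SEARCH_URL,
    FixtureTransport,
    InvalidTreeError,
    NotFoundError,
    build_search_query,
    complete_metadata,
    edge_list_to_newick,
    edges_from_newick,
    search_datasets,
)
from treeharvest.records import PublicationRecord
from treeharvest.treescan import validate_tree_file


class TestSearchDatasets:
    def test_dryad_downloadable_predicate(self):
        t = FixtureTransport()
        t.record(
            DRYAD_SEARCH_URL,
            {"q": "10.1/x"},
            {"_embedded": {"stash:datasets": [
                {"identifier": "12345", "storageSize": 2048},
                {"identifier": "", "storageSize": None},
            ]}},
        )
        hits = search_datasets("10.1/x", t, "dryad")
        assert [h.downloadable for h in hits] == [True, False]

    def test_figshare_requires_nonempty_files(self):
        t = FixtureTransport()
        t.record(
            FIGSHARE_SEARCH_URL,
            {"search_for": "10.1/y"},
            [{"id": 9, "files": []}, {"id": 10, "files": [{"name": "t.nwk"}]}],
        )
        hits = search_datasets("10.1/y", t, "figshare")
        assert [h.downloadable for h in hits] == [False, True]

    def test_empty_result_body(self):
        t = FixtureTransport()
        t.record(DRYAD_SEARCH_URL, {"q": "10.1/none"},
                 {"_embedded": {"stash:datasets": []}})
        assert search_datasets("10.1/none", t, "dryad") == []

    def test_unrecorded_request_is_empty(self):
        assert search_datasets("10.1/missing", FixtureTransport(), "dryad") == []

    def test_fixture_directory_round_trip(self, tmp_path):
        t = FixtureTransport()
        t.record(DRYAD_SEARCH_URL, {"q": "10.1/z"},
                 {"_embedded": {"stash:datasets": [{"identifier": "7", "storageSize": 1}]}})
        t.save(tmp_path)
        player = FixtureTransport(tmp_path)
        hits = search_datasets("10.1/z", player, "dryad")
        assert len(hits) == 1 and hits[0].downloadable

    def test_keyword_query_builder(self):
        q = build_search_query()
        assert "phylogeny" in q["q"] and "systematics" in q["q"]
        custom = build_search_query(("phylogenomics",), per_page=10)
        assert custom == {"q": "phylogenomics", "per_page": 10, "page": 1}


class TestCompleteMetadata:
    PAYLOAD = {
        "message": {
            "title": ["A dove phylogeny"],
            "author": [{"given": "A", "family": "Author"}],
            "container-title": ["Syst Biol"],
            "issued": {"date-parts": [[2024, 3, 2]]},
        }
    }

    def test_fills_record_from_payload(self):
        t = FixtureTransport()
        t.record(f"{CROSSREF_WORKS_URL}/10.1/d", {}, self.PAYLOAD)
        rec = complete_metadata("10.1/d", t)
        assert rec.title == "A dove phylogeny"
        assert rec.authors == ["A Author"]
        assert rec.journal == "Syst Biol"
        assert rec.pub_date == "2024-03-02"

    def test_unknown_doi_not_found(self):
        with pytest.raises(NotFoundError):
            complete_metadata("10.1/unknown", FixtureTransport())

    def test_field_fill_leaves_present_fields_alone(self):
        t = FixtureTransport()
        t.record(f"{CROSSREF_WORKS_URL}/10.1/d", {}, self.PAYLOAD)
        base = PublicationRecord(doi="10.1/d", title="Original title")
        out = complete_metadata("10.1/d", t, base)
        assert out.title == "Original title"
        assert out.journal == "Syst Biol"


def clades(newick: str) -> set[frozenset]:
    """Leaf-label sets under every node, via an independent DendroPy parse."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    out = set()
    for node in tree.preorder_node_iter():
        leaves = frozenset(
            l.taxon.label if l.taxon else l.label for l in node.leaf_iter()
        )
        out.add(leaves)
    return out


def edge_clades(tree: EdgeListTree) -> set[frozenset]:
    children: dict[str, list[str]] = {}
    for p, c in tree.edges:
        children.setdefault(p, []).append(c)

    def leaves_under(n):
        kids = children.get(n, [])
        if not kids:
            return frozenset([tree.nodes[n]])
        return frozenset().union(*(leaves_under(k) for k in kids))

    return {leaves_under(n) for n in tree.nodes}


def random_edge_tree(rng: random.Random, n_leaves: int) -> EdgeListTree:
    nodes = {f"L{i}": f"Taxon_{i}" for i in range(n_leaves)}
    edges = set()
    roots = list(nodes)
    k = 0
    while len(roots) > 1:
        i, j = rng.sample(range(len(roots)), 2)
        a, b = roots[i], roots[j]
        parent = f"I{k}"
        k += 1
        nodes[parent] = None
        edges |= {(parent, a), (parent, b)}
        roots = [r for m, r in enumerate(roots) if m not in (i, j)] + [parent]
    return EdgeListTree(nodes=nodes, edges=edges, root_id=roots[0])


class TestEdgeListToNewick:
    def test_cherry(self):
        t = EdgeListTree(nodes={"r": None, "a": "A", "b": "B"},
                         edges={("r", "a"), ("r", "b")}, root_id="r")
        assert edge_list_to_newick(t) == "(A,B);"

    def test_star_children_sorted_by_label(self):
        nodes = {"r": None, "1": "C", "2": "A", "3": "D", "4": "B"}
        edges = {("r", x) for x in "1234"}
        t = EdgeListTree(nodes=nodes, edges=edges, root_id="r")
        assert edge_list_to_newick(t) == "(A,B,C,D);"

    def test_labels_needing_quotes(self):
        t = EdgeListTree(nodes={"r": None, "a": "Homo sapiens", "b": "B"},
                         edges={("r", "a"), ("r", "b")}, root_id="r")
        newick = edge_list_to_newick(t)
        rec = validate_tree_file(newick.encode(), "q.nwk")
        assert rec.valid and "Homo sapiens" in rec.tip_labels

    @pytest.mark.parametrize(
        "nodes,edges,root,err",
        [
            ({"r": None, "a": "A"}, {("r", "a"), ("a", "r")}, "r", "parent"),
            ({"r": None, "a": "A", "x": "X"}, {("r", "a")}, "r", "disconnected"),
            ({"r": None, "a": None, "b": "B"}, {("r", "a"), ("r", "b")}, "r", "label"),
            ({"r": None, "a": "A"}, {("r", "q")}, "r", "unknown"),
        ],
    )
    def test_invalid_structures_raise(self, nodes, edges, root, err):
        with pytest.raises(InvalidTreeError, match=err):
            edge_list_to_newick(EdgeListTree(nodes=nodes, edges=edges, root_id=root))

    def test_random_trees_topology_round_trip(self):
        rng = random.Random(13)
        for _ in range(200):
            t = random_edge_tree(rng, rng.randint(2, 25))
            newick = edge_list_to_newick(t)
            assert clades(newick) == edge_clades(t)

    def test_newick_decomposition_inverts(self):
        rng = random.Random(14)
        for _ in range(50):
            t = random_edge_tree(rng, rng.randint(2, 12))
            newick = edge_list_to_newick(t)
            again = edge_list_to_newick(edges_from_newick(newick))
            assert again == newick
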