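"""Repository and metadata API contracts, testable offline.

Clients are pure functions of an injected *transport* — any callable
``transport(url, params) -> (status, json_body)``.  A recorded-fixture
transport replays canned responses keyed by a hash of the request, so every
test is hermetic; a live HTTP transport can be plugged in by callers that
opt into network access.

Also here: reconstruction of Newick strings from node-link (edge table)
tree dumps, the storage model used by legacy tree repositories.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from .records import PublicationRecord, normalize_doi

Transport = Callable[[str, dict], tuple[int, dict | list | None]]

DRYAD_SEARCH_URL = "https://datadryad.org/api/v2/search"
FIGSHARE_SEARCH_URL = "https://api.figshare.com/v2/articles/search"
CROSSREF_WORKS_URL = "https://api.crossref.org/works"

#: Keyword set for orphan-record harvesting queries.
DEFAULT_KEYWORDS = ("phylogeny", "phylogenetics", "evolution", "systematics")


class TransportError(RuntimeError):
    """Transport failed after retries."""


class SchemaError(ValueError):
    """Response did not match the expected source schema."""


class NotFoundError(LookupError):
    """The queried DOI is unknown to the metadata service."""


def request_key(url: str, params: dict) -> str:
    """Stable hash of one request, used to key recorded fixtures."""
    blob = json.dumps([url, params], sort_keys=True).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:24]


class FixtureTransport:
    """Replays recorded responses: request-hash -> response body JSON files.

    Responses can be registered in memory via :meth:`record` or loaded from a
    directory of ``<hash>.json`` files.  Unknown requests return HTTP 404.
    """

    def __init__(self, fixture_dir: str | Path | None = None) -> None:
        self._responses: dict[str, tuple[int, object]] = {}
        self._dir = Path(fixture_dir) if fixture_dir else None

    def record(self, url: str, params: dict, body: object, status: int = 200) -> str:
        key = request_key(url, params)
        self._responses[key] = (status, body)
        return key

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for key, (status, body) in self._responses.items():
            (d / f"{key}.json").write_text(
                json.dumps({"status": status, "body": body}, sort_keys=True), "utf-8"
            )

    def __call__(self, url: str, params: dict) -> tuple[int, object]:
        key = request_key(url, params)
        if key in self._responses:
            return self._responses[key]
        if self._dir is not None:
            path = self._dir / f"{key}.json"
            if path.exists():
                payload = json.loads(path.read_text("utf-8"))
                return payload.get("status", 200), payload.get("body")
        return 404, None


def _call(transport: Transport, url: str, params: dict, retries: int = 2) -> tuple[int, object]:
    last: Exception | None = None
    for _ in range(retries + 1):
        try:
            return transport(url, params)
        except Exception as exc:  # transient transport failure
            last = exc
    raise TransportError(f"transport failed for {url}: {last}")


@dataclass(frozen=True)
class RepositoryHit:
    """One search hit from a data repository."""

    source: str  # "dryad" | "figshare"
    identifier: str
    storage_size: int | None = None
    files: tuple = ()
    related_doi: str | None = None

    @property
    def downloadable(self) -> bool:
        """Whether the hit satisfies the per-source downloadability predicate.

        Dryad hits need a non-empty identifier and a storageSize; FigShare
        hits need a non-empty files list.
        """
        if self.source == "dryad":
            return bool(self.identifier) and self.storage_size is not None
        if self.source == "figshare":
            return len(self.files) > 0
        return False


def build_search_query(
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS, *, per_page: int = 100, page: int = 1
) -> dict:
    """Keyword-search parameters for orphan-record harvesting."""
    return {"q": " OR ".join(keywords), "per_page": per_page, "page": page}


def search_datasets(doi: str, transport: Transport, source: str = "dryad") -> list[RepositoryHit]:
    """Search one repository for datasets related to ``doi``."""
    doi = normalize_doi(doi)
    if source == "dryad":
        url, params = DRYAD_SEARCH_URL, {"q": doi}
    elif source == "figshare":
        url, params = FIGSHARE_SEARCH_URL, {"search_for": doi}
    else:
        raise ValueError(f"unknown repository source {source!r}")
    status, body = _call(transport, url, params)
    if status == 404 or body is None:
        return []
    hits: list[RepositoryHit] = []
    try:
        if source == "dryad":
            embedded = body.get("_embedded", {}).get("stash:datasets", [])
            for item in embedded:
                hits.append(
                    RepositoryHit(
                        source="dryad",
                        identifier=str(item.get("identifier", "") or ""),
                        storage_size=item.get("storageSize"),
                        related_doi=item.get("relatedPublicationDOI"),
                    )
                )
        else:
            items = body if isinstance(body, list) else body.get("items", [])
            for item in items:
                hits.append(
                    RepositoryHit(
                        source="figshare",
                        identifier=str(item.get("id", "") or ""),
                        files=tuple(item.get("files") or ()),
                        related_doi=item.get("resource_doi"),
                    )
                )
    except (AttributeError, TypeError) as exc:
        raise SchemaError(f"unexpected {source} response shape: {exc}") from exc
    return hits


def complete_metadata(
    doi: str, transport: Transport, base: PublicationRecord | None = None
) -> PublicationRecord:
    """Fill publication metadata for ``doi`` from a Crossref-style works payload.

    When ``base`` is given only its absent fields are filled (field-fill
    semantics); otherwise a fresh record is built from the payload.
    """
    doi = normalize_doi(doi)
    status, body = _call(transport, f"{CROSSREF_WORKS_URL}/{doi}", {})
    if status == 404 or body is None:
        raise NotFoundError(f"DOI not found: {doi}")
    msg = body.get("message", body) if isinstance(body, dict) else {}
    title_list = msg.get("title") or []
    title = title_list[0] if title_list else (base.title if base else "")
    authors = [
        " ".join(p for p in (a.get("given"), a.get("family")) if p)
        for a in msg.get("author", [])
    ]
    journal_list = msg.get("container-title") or []
    parts = (msg.get("issued", {}).get("date-parts") or [[None]])[0]
    pub_date = "-".join(f"{p:02d}" if i else str(p) for i, p in enumerate(parts) if p is not None) or None
    fetched = PublicationRecord(
        doi=doi,
        title=title or "(untitled)",
        authors=authors,
        abstract=msg.get("abstract"),
        journal=journal_list[0] if journal_list else None,
        pub_date=pub_date,
        source="crossref",
    )
    if base is None:
        return fetched
    base.merge_fill(fetched)
    return base


# ---------------------------------------------------------------------------
# Node-link tree reconstruction
# ---------------------------------------------------------------------------


class InvalidTreeError(ValueError):
    """Edge list is cyclic, disconnected, or not rooted at the stated root."""


@dataclass
class EdgeListTree:
    """A tree stored as nodes and parent->child links."""

    nodes: dict[str, str | None]  # node_id -> label (leaves labeled; internals may be None)
    edges: set[tuple[str, str]] = field(default_factory=set)
    root_id: str = ""


def _quote_label(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def edge_list_to_newick(tree: EdgeListTree, *, keep_internal_labels: bool = True) -> str:
    """Reconstruct a Newick string from a node-link tree dump.

    Children are emitted in deterministic order (sorted by the smallest leaf
    label under each child).  Raises :class:`InvalidTreeError` on cycles,
    disconnection, unlabeled leaves, or a child with two parents.
    """
    children: dict[str, list[str]] = {}
    indegree: dict[str, int] = {n: 0 for n in tree.nodes}
    for parent, child in tree.edges:
        if parent not in tree.nodes or child not in tree.nodes:
            raise InvalidTreeError(f"edge ({parent},{child}) references unknown node")
        children.setdefault(parent, []).append(child)
        indegree[child] += 1
        if indegree[child] > 1:
            raise InvalidTreeError(f"node {child} has multiple parents")
    if tree.root_id not in tree.nodes:
        raise InvalidTreeError(f"root {tree.root_id!r} not among nodes")
    if indegree.get(tree.root_id, 0) != 0:
        raise InvalidTreeError("stated root has a parent")

    visited: set[str] = set()

    def render(node: str) -> tuple[str, str]:
        """Returns (newick fragment, min leaf label under node)."""
        if node in visited:
            raise InvalidTreeError(f"cycle through node {node}")
        visited.add(node)
        kids = children.get(node, [])
        label = tree.nodes.get(node)
        if not kids:
            if not label:
                raise InvalidTreeError(f"leaf {node} has no label")
            return _quote_label(label), label
        rendered = sorted((render(k) for k in kids), key=lambda rk: rk[1])
        inner = ",".join(frag for frag, _ in rendered)
        tag = _quote_label(label) if (label and keep_internal_labels) else ""
        return f"({inner}){tag}", rendered[0][1]

    fragment, _ = render(tree.root_id)
    if len(visited) != len(tree.nodes):
        missing = set(tree.nodes) - visited
        raise InvalidTreeError(f"disconnected nodes: {sorted(missing)}")
    return fragment + ";"


def edges_from_newick(newick: str) -> EdgeListTree:
    """Inverse helper: decompose a Newick string into a node-link tree."""
    import dendropy

    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    nodes: dict[str, str | None] = {}
    edges: set[tuple[str, str]] = set()
    ids: dict[int, str] = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        nid = f"n{i}"
        ids[id(node)] = nid
        label = node.taxon.label if node.taxon is not None else node.label
        nodes[nid] = label
        if node.parent_node is not None:
            edges.add((ids[id(node.parent_node)], nid))
    root_id = ids[id(tree.seed_node)]
    return EdgeListTree(nodes=nodes, edges=edges, root_id=root_id)
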