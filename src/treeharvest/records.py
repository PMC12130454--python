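"""Publication records, DOI deduplication and dataset export.

A study is keyed by its canonical DOI (lowercased, resolver prefix
stripped).  Deduplication keeps the first occurrence per DOI and merges
later duplicates field-wise, filling only absent fields.  The export
produces the two-part dataset layout — a JSON array of per-study records
whose ``tree_files`` field lists tree IDs, plus a ZIP archive holding one
Newick file per tree ID — and round-trips losslessly through ``import``.
A relational projection into six flat tables (Study, Tree, TreeFile,
Taxonomy, Matrix, Submit) is provided for database loading.
"""

from __future__ import annotations

import io
import json
import re
import zipfile
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone

from .reconcile import AssignmentResult, Confidence

PIPELINE_VERSION = "0.1.0"

SOURCES = {"pubmed", "wos", "dryad", "figshare", "treebase", "crossref", "fixture"}


class DOIError(ValueError):
    """Raised when a string cannot be canonicalized into a DOI."""


def normalize_doi(raw: str) -> str:
    """Canonical DOI: prefix-stripped, trimmed, lowercase, starting "10."."""
    s = raw.strip()
    for prefix in ("https://doi.org/", "http://doi.org/", "https://dx.doi.org/",
                   "http://dx.doi.org/", "doi.org/", "doi:"):
        if s.lower().startswith(prefix):
            s = s[len(prefix):]
            break
    s = s.strip().lower()
    if not s.startswith("10."):
        raise DOIError(f"not a DOI: {raw!r}")
    return s


def doi_slug(doi: str) -> str:
    """Filesystem-safe slug of a canonical DOI."""
    return re.sub(r"[^a-z0-9.]+", "-", doi)


@dataclass
class PublicationRecord:
    """Bibliographic metadata of one study, keyed by canonical DOI."""

    doi: str
    title: str
    authors: list[str] = field(default_factory=list)
    abstract: str | None = None
    journal: str | None = None
    pub_date: str | None = None
    source: str = "fixture"

    def __post_init__(self) -> None:
        self.doi = normalize_doi(self.doi)
        if not self.title.strip():
            raise ValueError("publication title must be non-empty")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    def merge_fill(self, other: "PublicationRecord") -> None:
        """Fill absent fields from ``other`` without overwriting present ones."""
        if not self.authors:
            self.authors = list(other.authors)
        for name in ("abstract", "journal", "pub_date"):
            if getattr(self, name) in (None, ""):
                setattr(self, name, getattr(other, name))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PublicationRecord":
        return cls(
            doi=d["doi"],
            title=d["title"],
            authors=list(d.get("authors", [])),
            abstract=d.get("abstract"),
            journal=d.get("journal"),
            pub_date=d.get("pub_date"),
            source=d.get("source", "fixture"),
        )


def dedupe(records: list[PublicationRecord]) -> list[PublicationRecord]:
    """Keep the first record per DOI (stable order), field-fill from later ones."""
    seen: dict[str, PublicationRecord] = {}
    out: list[PublicationRecord] = []
    for rec in records:
        if rec.doi in seen:
            seen[rec.doi].merge_fill(rec)
        else:
            seen[rec.doi] = rec
            out.append(rec)
    return out


@dataclass
class StudyRecord:
    """One curated study: publication, its validated tree file IDs, assignment."""

    publication: PublicationRecord
    tree_files: list[str] = field(default_factory=list)
    assignment: AssignmentResult | None = None

    def __post_init__(self) -> None:
        if len(set(self.tree_files)) != len(self.tree_files):
            raise ValueError("tree file IDs must be unique within a record")


def assign_tree_ids(doi: str, n: int) -> list[str]:
    """Deterministic tree IDs "{doi-slug}.{ordinal}" so re-runs reproduce."""
    slug = doi_slug(normalize_doi(doi))
    return [f"{slug}.{i}" for i in range(1, n + 1)]


class ExportError(ValueError):
    """Raised when export references tree IDs missing from the tree store."""


def export_dataset(
    records: list[StudyRecord], tree_store: dict[str, str]
) -> tuple[bytes, bytes]:
    """Serialize studies to (Paper.json bytes, Tree.zip bytes).

    ``tree_store`` maps tree ID -> Newick text.  Every tree ID referenced in
    a record must be present; archive members are named exactly by tree ID.
    """
    dangling = [
        tid for rec in records for tid in rec.tree_files if tid not in tree_store
    ]
    if dangling:
        raise ExportError(f"dangling tree IDs: {sorted(set(dangling))}")

    payload = []
    for rec in records:
        obj = rec.publication.to_dict()
        obj["tree_files"] = list(rec.tree_files)
        obj["assignment"] = rec.assignment.to_dict() if rec.assignment else None
        payload.append(obj)
    json_bytes = json.dumps(payload, ensure_ascii=False, sort_keys=True, indent=1).encode(
        "utf-8"
    )

    buf = io.BytesIO()
    referenced = [tid for rec in records for tid in rec.tree_files]
    with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as zf:
        for tid in referenced:
            zf.writestr(tid, tree_store[tid])
    return json_bytes, buf.getvalue()


def import_dataset(
    json_bytes: bytes, archive_bytes: bytes
) -> tuple[list[StudyRecord], dict[str, str]]:
    """Inverse of :func:`export_dataset`."""
    payload = json.loads(json_bytes.decode("utf-8"))
    records: list[StudyRecord] = []
    for obj in payload:
        pub = PublicationRecord.from_dict(obj)
        assignment = (
            AssignmentResult.from_dict(obj["assignment"])
            if obj.get("assignment")
            else None
        )
        records.append(
            StudyRecord(
                publication=pub,
                tree_files=list(obj.get("tree_files", [])),
                assignment=assignment,
            )
        )
    store: dict[str, str] = {}
    with zipfile.ZipFile(io.BytesIO(archive_bytes)) as zf:
        for name in zf.namelist():
            store[name] = zf.read(name).decode("utf-8")
    return records, store


def to_relational_rows(
    records: list[StudyRecord],
    tree_store: dict[str, str] | None = None,
    *,
    harvested_at: str | None = None,
) -> dict[str, list[dict]]:
    """Project studies into the six flat tables used for database loading.

    Tables are one-to-one associated through synthetic primary keys.  Matrix
    rows are emitted empty: alignment harvesting is out of scope.
    """
    if harvested_at is None:
        harvested_at = datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
    tables: dict[str, list[dict]] = {
        "Study": [],
        "Tree": [],
        "TreeFile": [],
        "Taxonomy": [],
        "Matrix": [],
        "Submit": [],
    }
    tree_pk = 0
    for study_pk, rec in enumerate(records, start=1):
        pub = rec.publication
        tables["Study"].append(
            {
                "study_pk": study_pk,
                "doi": pub.doi,
                "title": pub.title,
                "authors": "; ".join(pub.authors),
                "abstract": pub.abstract or "",
                "journal": pub.journal or "",
                "pub_date": pub.pub_date or "",
            }
        )
        a = rec.assignment
        tables["Taxonomy"].append(
            {
                "taxonomy_pk": study_pk,
                "study_pk": study_pk,
                "name": (a.final_name if a else None) or "",
                "rank": (a.final_rank if a else None) or "",
                "confidence": a.confidence.value if a else Confidence.UNDETERMINED.value,
            }
        )
        tables["Submit"].append(
            {
                "submit_pk": study_pk,
                "study_pk": study_pk,
                "source": pub.source,
                "harvested_at": harvested_at,
                "pipeline_version": PIPELINE_VERSION,
            }
        )
        for tid in rec.tree_files:
            tree_pk += 1
            tables["Tree"].append(
                {"tree_pk": tree_pk, "study_pk": study_pk, "tree_id": tid}
            )
            content = (tree_store or {}).get(tid, "")
            tables["TreeFile"].append(
                {
                    "treefile_pk": tree_pk,
                    "tree_pk": tree_pk,
                    "format": "newick",
                    "size_bytes": len(content.encode("utf-8")),
                }
            )
    return tables
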