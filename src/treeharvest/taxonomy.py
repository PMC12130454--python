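"""Rank-restricted taxonomy index.

Loads a taxonomy table in the NCBI taxdump dialect (pipe-delimited
``names.dmp``/``nodes.dmp`` pairs) or a simple TSV dialect and exposes the
four name sets used for taxonomic assignment — order, family, genus and
species — together with a homonym-aware, case-insensitive lookup.

Only the four target ranks are indexed; every other rank is discarded.
Only "scientific name" rows are used when a name-class column is present;
synonyms and common names are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

logger = logging.getLogger(__name__)

#: The ranks retained by the index, broadest first.  Broader-rank-first
#: ordering is also the tie-break used when candidate names compete.
TARGET_RANKS: tuple[str, ...] = ("order", "family", "genus", "species")

_RANK_ORDER = {rank: i for i, rank in enumerate(TARGET_RANKS)}


class TaxonomyError(ValueError):
    """Raised for unusable taxonomy sources (empty or malformed in strict mode)."""


def rank_sort_key(rank: str) -> int:
    """Broadest rank first: order < family < genus < species."""
    return _RANK_ORDER[rank]


def canonical_name(name: str, rank: str) -> str:
    """Canonical capitalization: first word capitalized, species epithet lowercased."""
    parts = name.split()
    if not parts:
        return name
    head = parts[0][:1].upper() + parts[0][1:].lower()
    if rank == "species":
        tail = [p.lower() for p in parts[1:]]
    else:
        tail = parts[1:]
    return " ".join([head] + tail)


@dataclass(frozen=True)
class TaxonEntry:
    """One taxon: identifier, canonical scientific name, rank, optional parent."""

    taxon_id: str
    name: str
    rank: str
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise TaxonomyError("taxon name must be non-empty")
        if self.rank not in TARGET_RANKS:
            raise TaxonomyError(f"rank must be one of {TARGET_RANKS}, got {self.rank!r}")
        if self.rank == "species" and len(self.name.split()) < 2:
            raise TaxonomyError(f"species name needs >=2 words: {self.name!r}")


@dataclass
class TaxonomyIndex:
    """Four rank-restricted name sets with homonym-aware lookup.

    Matching is case-insensitive; canonical capitalization is stored.  The
    ``homonyms`` map contains every spelling claimed by two or more distinct
    taxon ids (within or across ranks) — e.g. *Mya* the clam genus colliding
    with a planted family of the same spelling.
    """

    entries: list[TaxonEntry] = field(default_factory=list)
    #: rank -> set of canonical names at that rank
    rank_sets: dict[str, set[str]] = field(
        default_factory=lambda: {r: set() for r in TARGET_RANKS}
    )
    #: casefolded name -> set of (rank, taxon_id)
    _by_key: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    #: casefolded name -> canonical spelling (first seen)
    _canonical: dict[str, str] = field(default_factory=dict)
    warnings: int = 0

    def add(self, entry: TaxonEntry) -> None:
        name = canonical_name(entry.name, entry.rank)
        entry = TaxonEntry(entry.taxon_id, name, entry.rank, entry.parent_id)
        self.entries.append(entry)
        self.rank_sets[entry.rank].add(name)
        key = name.casefold()
        self._by_key.setdefault(key, set()).add((entry.rank, entry.taxon_id))
        self._canonical.setdefault(key, name)

    def lookup(self, token: str) -> set[tuple[str, str]]:
        """All (rank, taxon_id) pairs whose name matches ``token`` case-insensitively."""
        if not token:
            return set()
        return set(self._by_key.get(token.casefold(), set()))

    def canonical(self, token: str) -> str | None:
        """Stored canonical spelling for a matching token, or None."""
        return self._canonical.get(token.casefold())

    def ranks_of(self, token: str) -> set[str]:
        return {rank for rank, _ in self.lookup(token)}

    def parent_of(self, taxon_id: str) -> str | None:
        for e in self.entries:
            if e.taxon_id == taxon_id:
                return e.parent_id
        return None

    def is_homonym(self, token: str) -> bool:
        return len(self.lookup(token)) >= 2

    @property
    def homonyms(self) -> dict[str, set[tuple[str, str]]]:
        """Every spelling mapping to >=2 distinct taxon ids."""
        return {
            self._canonical[k]: set(v)
            for k, v in self._by_key.items()
            if len({tid for _, tid in v}) >= 2
        }

    def names_at(self, rank: str) -> set[str]:
        return set(self.rank_sets[rank])

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonomyIndex):
            return NotImplemented
        return self.rank_sets == other.rank_sets and self._by_key == other._by_key


def _split_taxdump_row(line: str) -> list[str]:
    # taxdump rows: fields separated by "\t|\t", terminated "\t|"
    line = line.rstrip("\r\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


def _iter_rows(source: Iterable[str] | IO[str]) -> Iterator[str]:
    for line in source:
        if line.strip():
            yield line


def load_taxonomy(
    names_source: Iterable[str] | IO[str],
    nodes_source: Iterable[str] | IO[str] | None = None,
    *,
    strict: bool = False,
) -> TaxonomyIndex:
    """Build a :class:`TaxonomyIndex` from taxdump-dialect or simple-TSV text.

    Parameters
    ----------
    names_source
        Lines of ``names.dmp`` (taxid | name | unique name | name class) or of
        the single-file TSV dialect ``taxon_id<TAB>name<TAB>rank<TAB>parent_id``.
    nodes_source
        Lines of ``nodes.dmp`` (taxid | parent | rank | ...).  Optional: when
        absent the names source must carry its own rank column (TSV dialect).
    strict
        When True any malformed row raises :class:`TaxonomyError`; the default
        tolerant mode logs a warning, counts it and skips the row.

    Raises
    ------
    TaxonomyError
        If no indexable entry at the four target ranks is found.
    """
    index = TaxonomyIndex()

    def bad_row(msg: str) -> None:
        if strict:
            raise TaxonomyError(msg)
        index.warnings += 1
        logger.warning("skipping taxonomy row: %s", msg)

    ranks: dict[str, tuple[str, str | None]] = {}
    if nodes_source is not None:
        for line in _iter_rows(nodes_source):
            fields = _split_taxdump_row(line) if "\t|" in line else line.rstrip("\n").split("\t")
            if len(fields) < 3:
                bad_row(f"nodes row with {len(fields)} fields: {line!r}")
                continue
            taxid, parent, rank = fields[0].strip(), fields[1].strip(), fields[2].strip()
            ranks[taxid] = (rank.lower(), parent or None)

    for line in _iter_rows(names_source):
        taxdump = "\t|" in line
        fields = _split_taxdump_row(line) if taxdump else line.rstrip("\n").split("\t")
        fields = [f.strip() for f in fields]
        if taxdump:
            # names.dmp: taxid | name | unique name | name class
            if len(fields) < 2:
                bad_row(f"names row with {len(fields)} fields: {line!r}")
                continue
            taxid, name = fields[0], fields[1]
            name_class = fields[3] if len(fields) >= 4 else "scientific name"
            if name_class and name_class != "scientific name":
                continue
            if nodes_source is None:
                bad_row("taxdump names row without nodes source (no rank available)")
                continue
            if taxid not in ranks:
                bad_row(f"taxid {taxid} absent from nodes source")
                continue
            rank, parent = ranks[taxid]
        else:
            # TSV dialect: taxon_id, name, rank[, parent_id]
            if len(fields) < 3:
                bad_row(f"TSV row with {len(fields)} fields: {line!r}")
                continue
            taxid, name, rank = fields[0], fields[1], fields[2].lower()
            parent = fields[3] if len(fields) >= 4 and fields[3] else None
            if nodes_source is not None and taxid in ranks:
                rank, parent = ranks[taxid][0], ranks[taxid][1] or parent
        if rank not in TARGET_RANKS:
            continue
        try:
            index.add(TaxonEntry(taxid, name, rank, parent))
        except TaxonomyError as exc:
            bad_row(str(exc))

    if not index.entries:
        raise TaxonomyError("empty taxonomy: no entries at ranks order/family/genus/species")
    return index
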