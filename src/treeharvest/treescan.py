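"""Tree-file discovery, validation and the tree-derived taxon candidate.

The discovery step expands archives (ZIP/TAR/GZ, recursively to a depth
limit) and keeps exactly the files whose suffix — compared case-insensitively
— is one of the eight whitelisted tree suffixes.  Validation parses each
survivor as Newick, then NEXUS (TRANSLATE tables resolved), via DendroPy and
records tip-label multisets.  Tip labels are normalized into candidate taxon
strings (full label, leading binomial, leading genus word) and intersected
with the taxonomy rank sets to produce the tree-derived candidate, with
duplicate matches counted.
"""

from __future__ import annotations

import gzip
import io
import logging
import tarfile
import zipfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import dendropy

from .taxonomy import TaxonomyIndex
from .textmine import CandidateName, select_candidate

logger = logging.getLogger(__name__)

#: Filename suffixes accepted as candidate tree files (compared ignoring case).
TREE_SUFFIXES: frozenset[str] = frozenset(
    {".nwk", ".newick", ".nex", ".nexus", ".tre", ".tree", ".treefile", ".txt"}
)
ARCHIVE_SUFFIXES: frozenset[str] = frozenset({".zip", ".tar", ".gz", ".tgz"})
MAX_ARCHIVE_DEPTH = 3

#: Name2 credibility floor: top match must occur at least this many times ...
MIN_CANDIDATE_COUNT = 2
#: ... or cover at least this fraction of pooled tips.
MIN_CANDIDATE_FRACTION = 0.10


@dataclass(frozen=True)
class FileEntry:
    """A candidate file: display name plus raw bytes."""

    name: str
    data: bytes
    origin: str = ""

    @classmethod
    def from_path(cls, path: str | Path) -> "FileEntry":
        p = Path(path)
        return cls(name=p.name, data=p.read_bytes(), origin=str(p))


@dataclass
class TreeFileRecord:
    """One validated (or rejected) tree file."""

    file_id: str
    origin_path: str
    format: str | None  # "newick" | "nexus" | None
    tree_count: int
    tip_labels: Counter
    valid: bool
    reason: str | None = None  # failure code when valid is False
    newick: str = ""  # canonical Newick serialization of all trees

    @property
    def tip_count(self) -> int:
        return sum(self.tip_labels.values())


def has_tree_suffix(name: str) -> bool:
    """True iff the filename's suffix is in the 8-item whitelist, any case."""
    return Path(name).suffix.lower() in TREE_SUFFIXES


def _is_archive(name: str) -> bool:
    return Path(name).suffix.lower() in ARCHIVE_SUFFIXES


def _expand_archive(entry: FileEntry, depth: int) -> list[FileEntry]:
    """Recursively expand one archive entry; corrupt archives are skipped."""
    if depth > MAX_ARCHIVE_DEPTH:
        logger.warning("archive depth limit exceeded at %s; subtree skipped", entry.name)
        return []
    suffix = Path(entry.name).suffix.lower()
    children: list[FileEntry] = []
    try:
        if suffix == ".zip":
            with zipfile.ZipFile(io.BytesIO(entry.data)) as zf:
                for info in zf.infolist():
                    if info.is_dir():
                        continue
                    children.append(
                        FileEntry(
                            name=Path(info.filename).name,
                            data=zf.read(info),
                            origin=f"{entry.origin or entry.name}/{info.filename}",
                        )
                    )
        elif suffix in {".tar", ".tgz"} or entry.name.lower().endswith(".tar.gz"):
            with tarfile.open(fileobj=io.BytesIO(entry.data)) as tf:
                for member in tf.getmembers():
                    if not member.isfile():
                        continue
                    fh = tf.extractfile(member)
                    if fh is None:
                        continue
                    children.append(
                        FileEntry(
                            name=Path(member.name).name,
                            data=fh.read(),
                            origin=f"{entry.origin or entry.name}/{member.name}",
                        )
                    )
        elif suffix == ".gz":
            inner = Path(entry.name).stem  # drop the .gz
            children.append(
                FileEntry(
                    name=inner,
                    data=gzip.decompress(entry.data),
                    origin=f"{entry.origin or entry.name}/{inner}",
                )
            )
        else:  # pragma: no cover - guarded by _is_archive
            return []
    except Exception as exc:
        logger.warning("corrupt archive %s skipped: %s", entry.name, exc)
        return []
    out: list[FileEntry] = []
    for child in children:
        if _is_archive(child.name):
            out.extend(_expand_archive(child, depth + 1))
        else:
            out.append(child)
    return out


def discover_tree_files(entries: list[FileEntry | str | Path]) -> list[FileEntry]:
    """Expand archives, then keep files with a whitelisted tree suffix."""
    flat: list[FileEntry] = []
    for item in entries:
        entry = item if isinstance(item, FileEntry) else FileEntry.from_path(item)
        if _is_archive(entry.name):
            flat.extend(_expand_archive(entry, 1))
        else:
            flat.append(entry)
    return [e for e in flat if has_tree_suffix(e.name)]


def _decode(content: bytes) -> str | None:
    for encoding in ("utf-8", "latin-1"):
        try:
            return content.decode(encoding)
        except (UnicodeDecodeError, ValueError):
            continue
    return None


def _try_parse(text: str, schema: str) -> dendropy.TreeList | None:
    # First pass binds leaf labels to taxa so NEXUS TRANSLATE tables resolve;
    # duplicate tip labels (multiset semantics) need the label-only retry.
    for extra in ({}, {"suppress_leaf_node_taxa": True}):
        try:
            trees = dendropy.TreeList.get(
                data=text,
                schema=schema,
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
                **extra,
            )
        except Exception:
            continue
        if trees:
            return trees
    return None


def validate_tree_file(content: bytes | str, name: str) -> TreeFileRecord:
    """Parse ``content`` as Newick then NEXUS; record format, counts and tips.

    A valid record has at least one tree and every tree at least two tips.
    Failures return ``valid=False`` with a reason code (``encoding``,
    ``parse`` or ``degenerate``).
    """
    text = content if isinstance(content, str) else _decode(content)
    if text is None:
        return TreeFileRecord(name, name, None, 0, Counter(), False, reason="encoding")
    text = text.strip()
    trees = None
    fmt = None
    stripped = text.lstrip("﻿ \t\r\n")
    if stripped.upper().startswith("#NEXUS"):
        trees, fmt = _try_parse(text, "nexus"), "nexus"
    elif "(" in text and ";" in text:
        trees, fmt = _try_parse(text, "newick"), "newick"
        if trees is None:
            trees, fmt = _try_parse(text, "nexus"), "nexus"
    if trees is None:
        return TreeFileRecord(name, name, None, 0, Counter(), False, reason="parse")

    tips: Counter = Counter()
    for tree in trees:
        leaves = [leaf for leaf in tree.leaf_node_iter()]
        if len(leaves) < 2:
            return TreeFileRecord(
                name, name, fmt, len(trees), Counter(), False, reason="degenerate"
            )
        for leaf in leaves:
            label = leaf.taxon.label if leaf.taxon is not None else (leaf.label or "")
            tips[label] += 1
    newick = trees.as_string(
        schema="newick", suppress_rooting=True, suppress_leaf_node_labels=False
    )
    return TreeFileRecord(
        file_id=name,
        origin_path=name,
        format=fmt,
        tree_count=len(trees),
        tip_labels=tips,
        valid=True,
        newick=newick,
    )


def _looks_like_accession(token: str) -> bool:
    # trailing ids: all digits, or uppercase-letters-and-digits with a digit
    if token.isdigit():
        return True
    return (
        token.isupper()
        and any(c.isdigit() for c in token)
        and all(c.isalnum() for c in token)
    )


def normalize_tip_label(raw: str) -> list[str]:
    """Candidate taxon strings for one tip label, most specific first.

    Underscores and pipes become spaces, surrounding quotes are stripped and
    trailing accession-like tokens dropped; emits the cleaned full string,
    the leading two-word binomial (Capitalized + lowercase) when present, and
    the leading genus word.
    """
    if not raw:
        return []
    s = raw.replace("_", " ").replace("|", " ").strip()
    s = s.strip("'\"").strip()
    tokens = [t for t in s.split() if t]
    while tokens and _looks_like_accession(tokens[-1]):
        tokens.pop()
    if not tokens:
        return []
    candidates: list[str] = []
    full = " ".join(tokens)
    if (
        len(tokens) >= 2
        and tokens[0][:1].isupper()
        and tokens[1].islower()
        and tokens[1].isalpha()
    ):
        candidates.append(f"{tokens[0]} {tokens[1]}")
    if full not in candidates:
        candidates.insert(0, full) if len(tokens) > 2 else candidates.append(full)
    genus = tokens[0]
    if genus.isalpha() and genus not in candidates:
        candidates.append(genus)
    return candidates


def pooled_matches(
    records: list[TreeFileRecord], index: TaxonomyIndex
) -> tuple[Counter, int]:
    """Count rank-set matches over all tip labels of all valid records.

    Returns (matches keyed by (canonical name, rank), pooled tip count).
    Duplicate tips count as-is; a matched species binomial also increments
    its genus, since abbreviated labels often resolve only to genus level.
    """
    matches: Counter = Counter()
    pooled_tips = 0
    for record in records:
        if not record.valid:
            continue
        for raw, n in record.tip_labels.items():
            pooled_tips += n
            matched_ranks: set[str] = set()
            for candidate in normalize_tip_label(raw):
                for rank in index.ranks_of(candidate):
                    if rank in matched_ranks:
                        continue
                    matched_ranks.add(rank)
                    canonical = index.canonical(candidate) or candidate
                    matches[(canonical, rank)] += n
                    if rank == "species":
                        genus_word = canonical.split()[0]
                        if "genus" in index.ranks_of(genus_word) and "genus" not in matched_ranks:
                            matched_ranks.add("genus")
                            matches[(index.canonical(genus_word) or genus_word, "genus")] += n
    return matches, pooled_tips


def candidate_from_tree(
    records: list[TreeFileRecord],
    index: TaxonomyIndex,
    *,
    min_count: int = MIN_CANDIDATE_COUNT,
    min_fraction: float = MIN_CANDIDATE_FRACTION,
) -> CandidateName | None:
    """Name2: the highest-frequency rank-set match over pooled tip labels.

    Returns None when nothing matches or the top match fails the credibility
    floor (fewer than ``min_count`` occurrences and less than ``min_fraction``
    of pooled tips).
    """
    matches, pooled_tips = pooled_matches(records, index)
    triples = [(name, rank, n) for (name, rank), n in matches.items()]
    candidate = select_candidate(triples, "tree", index)
    if candidate is None:
        return None
    if candidate.frequency < min_count and (
        pooled_tips == 0 or candidate.frequency / pooled_tips < min_fraction
    ):
        return None
    return candidate
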