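"""Metadata-derived taxon candidates.

Tokenizes a publication's title and abstract, augments the token bag with
binomial species names (capitalized genus + lowercase epithet), removes the
most common English words, and intersects the survivors with the four
taxonomic rank sets.  The highest-frequency intersecting name becomes the
metadata candidate; alternatives and ambiguity (cross-rank homonyms such as
"Mya", or frequency ties) are recorded on the result.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .taxonomy import TaxonomyIndex, rank_sort_key

# Maximal runs of letters/digits, hyphen-joined runs kept whole.
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:-[A-Za-z0-9]+)*")
# Capitalized genus-like word followed by a lowercase epithet.
_BINOMIAL_RE = re.compile(r"\b([A-Z][a-z]{1,})[ \t]+([a-z]{2,})\b")


@lru_cache(maxsize=1)
def load_default_stopwords() -> frozenset[str]:
    """The bundled list of common English words, casefolded."""
    text = resources.files("treeharvest.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(w.strip().casefold() for w in text.splitlines() if w.strip())


def load_stopwords(path: str | None = None) -> frozenset[str]:
    """Stopwords from ``path`` (one word per line, UTF-8) or the bundled list."""
    if path is None:
        return load_default_stopwords()
    with open(path, encoding="utf-8", errors="replace") as fh:
        return frozenset(w.strip().casefold() for w in fh if w.strip())


@dataclass
class TokenBag:
    """Tokens of one text: unique spellings, raw counts, and binomial pairs."""

    unique_tokens: set[str] = field(default_factory=set)
    token_counts: Counter = field(default_factory=Counter)
    binomials: set[str] = field(default_factory=set)

    def count(self, token: str) -> int:
        """Raw occurrence count, case-insensitive over stored spellings."""
        key = token.casefold()
        return sum(n for t, n in self.token_counts.items() if t.casefold() == key)


@dataclass
class CandidateName:
    """A proposed study-level taxon from one assignment method."""

    name: str
    rank: str
    method: str  # "metadata" | "tree"
    frequency: int = 1
    ambiguous: bool = False
    alternatives: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frequency < 1:
            raise ValueError("candidate frequency must be >= 1")

    def same_taxon(self, other: "CandidateName | None") -> bool:
        return (
            other is not None
            and self.name.casefold() == other.name.casefold()
            and self.rank == other.rank
        )


def tokenize(text: str) -> TokenBag:
    """Split ``text`` on whitespace/punctuation into a :class:`TokenBag`.

    Tokens are maximal runs of letters and digits; internal hyphens are kept
    so hyphenated terms survive whole.  Counts reflect the raw stream.
    """
    bag = TokenBag()
    tokens = _TOKEN_RE.findall(text)
    bag.token_counts = Counter(tokens)
    bag.unique_tokens = set(bag.token_counts)
    bag.binomials = extract_binomials(text)
    for b in bag.binomials:
        bag.unique_tokens.add(b)
        bag.token_counts[b] += _count_binomial(text, b)
    return bag


def _is_common_word(word: str, stopwords: frozenset[str]) -> bool:
    w = word.casefold()
    if w in stopwords:
        return True
    # simple inflections of common words ("occurs", "occurred", "changing")
    for suffix in ("s", "es", "ed", "ing"):
        if w.endswith(suffix) and w[: -len(suffix)] in stopwords:
            return True
    return False


def extract_binomials(text: str, stopwords: frozenset[str] | None = None) -> set[str]:
    """Adjacent (Capitalized, lowercase) word pairs read as species binomials.

    Pairs whose would-be epithet is a common English word or one of its
    inflections are rejected ("the genus Mya occurs" yields nothing), since a
    capitalized genus followed by ordinary prose is not a species name.
    """
    if stopwords is None:
        stopwords = load_default_stopwords()
    return {
        f"{g} {e}"
        for g, e in _BINOMIAL_RE.findall(text)
        if not _is_common_word(e, stopwords)
    }


def _count_binomial(text: str, binomial: str) -> int:
    genus, epithet = binomial.split(" ", 1)
    return len(re.findall(rf"\b{re.escape(genus)}\s+{re.escape(epithet)}\b", text))


def remove_stopwords(bag: TokenBag, stopwords: frozenset[str] | set[str]) -> TokenBag:
    """Drop stopword tokens (case-insensitive); binomials are never removed."""
    lowered = {w.casefold() for w in stopwords}
    keep = {
        t
        for t in bag.unique_tokens
        if t in bag.binomials or t.casefold() not in lowered
    }
    out = TokenBag(
        unique_tokens=keep,
        token_counts=Counter({t: n for t, n in bag.token_counts.items() if t in keep}),
        binomials=set(bag.binomials),
    )
    return out


def _match_rank_sets(
    tokens: set[str], counts: Counter, index: TaxonomyIndex
) -> list[tuple[str, str, int]]:
    """(canonical name, rank, frequency) for every token found in a rank set."""
    matches: dict[tuple[str, str], int] = {}
    for token in tokens:
        if not token or token.isdigit():
            continue
        pairs = index.lookup(token)
        if not pairs:
            continue
        canonical = index.canonical(token) or token
        freq = sum(n for t, n in counts.items() if t.casefold() == token.casefold())
        freq = max(freq, 1)
        for rank in {r for r, _ in pairs}:
            key = (canonical, rank)
            matches[key] = max(matches.get(key, 0), freq)
    return [(name, rank, n) for (name, rank), n in matches.items()]


def select_candidate(
    matches: list[tuple[str, str, int]], method: str, index: TaxonomyIndex
) -> CandidateName | None:
    """Pick the maximal-frequency match; broader rank wins ties, then spelling.

    Ambiguity is flagged when the winner is a cross-rank homonym in the index
    or when another distinct name ties its frequency.
    """
    if not matches:
        return None
    ordered = sorted(matches, key=lambda m: (-m[2], rank_sort_key(m[1]), m[0]))
    name, rank, freq = ordered[0]
    alternatives = [m for m in ordered[1:]]
    tied = any(n != name and f == freq for n, _, f in alternatives)
    ambiguous = index.is_homonym(name) or tied
    return CandidateName(
        name=name,
        rank=rank,
        method=method,
        frequency=freq,
        ambiguous=ambiguous,
        alternatives=alternatives,
    )


def candidate_from_metadata(
    record,
    index: TaxonomyIndex,
    stopwords: frozenset[str] | set[str] | None = None,
) -> CandidateName | None:
    """Name1: intersect the publication's refined token set with the rank sets.

    ``record`` needs ``title`` and (optionally) ``abstract`` attributes or
    keys.  Returns None when no token of the title+abstract matches any of
    the four rank sets.
    """
    if stopwords is None:
        stopwords = load_default_stopwords()
    title = getattr(record, "title", None) or (record.get("title") if isinstance(record, dict) else "")
    abstract = getattr(record, "abstract", None) or (
        record.get("abstract") if isinstance(record, dict) else ""
    )
    text = " ".join(part for part in (title, abstract) if part)
    bag = remove_stopwords(tokenize(text), stopwords)
    matches = _match_rank_sets(bag.unique_tokens, bag.token_counts, index)
    return select_candidate(matches, "metadata", index)
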