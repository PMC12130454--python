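"""Synthetic taxonomies, publication corpora and tree files with known truth.

Everything the pipeline consumes can be generated here deterministically
from a seed: a taxdump-dialect taxonomy with planted cross-rank homonyms, a
corpus of publication records whose title/abstract embed each study's true
taxon among common-word filler, and Newick tree files whose tip labels
follow a fidelity model (exact binomial, genus-only or one-letter
abbreviation, or mangled beyond recognition).  The stored ground truth
supports stratified accuracy audits of the whole assignment pipeline.
"""

from __future__ import annotations

import io
import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .taxonomy import TaxonomyIndex, load_taxonomy
from .textmine import load_default_stopwords

FIDELITIES = ("exact", "abbreviated", "noisy")

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"


def _coin_word(rng: random.Random, syllables: int = 3) -> str:
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(syllables)
    )


def _fresh_word(rng: random.Random, used: set[str], syllables: int = 3) -> str:
    while True:
        w = _coin_word(rng, syllables)
        if w not in used:
            used.add(w)
            return w


@dataclass
class SyntheticTaxonomy:
    """A generated taxonomy: taxdump text plus its ground truth."""

    names_text: str
    nodes_text: str
    orders: list[str] = field(default_factory=list)
    families: list[str] = field(default_factory=list)
    genera: dict[str, list[str]] = field(default_factory=dict)  # genus -> species list
    homonyms: list[str] = field(default_factory=list)  # planted duplicate spellings
    seed: int = 0

    def load(self) -> TaxonomyIndex:
        return load_taxonomy(
            io.StringIO(self.names_text), io.StringIO(self.nodes_text)
        )

    def write(self, directory: str | Path) -> tuple[Path, Path]:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        names = d / "names.dmp"
        nodes = d / "nodes.dmp"
        names.write_text(self.names_text, "utf-8")
        nodes.write_text(self.nodes_text, "utf-8")
        return names, nodes


def generate_taxonomy(
    seed: int,
    n_orders: int = 3,
    families_per_order: int = 3,
    genera_per_family: int = 4,
    species_per_genus: int = 5,
    n_homonyms: int = 0,
) -> SyntheticTaxonomy:
    """Emit a taxdump-dialect taxonomy with exact counts and planted homonyms.

    Homonyms are planted by renaming ``n_homonyms`` families to the spelling
    of a genus from a different family, producing cross-rank duplicate
    spellings (two distinct taxon ids per planted name).
    """
    if min(n_orders, families_per_order, genera_per_family, species_per_genus) < 1:
        raise ValueError("all taxonomy counts must be >= 1")
    rng = random.Random(seed)
    used: set[str] = set()
    rows: list[tuple[str, str, str, str]] = []  # (taxid, name, rank, parent)
    orders: list[str] = []
    families: list[str] = []
    genera: dict[str, list[str]] = {}
    family_of_genus: dict[str, str] = {}
    next_id = 1

    def new_id() -> str:
        nonlocal next_id
        tid = str(next_id)
        next_id += 1
        return tid

    for _ in range(n_orders):
        order = _fresh_word(rng, used).capitalize() + "iformes"
        oid = new_id()
        rows.append((oid, order, "order", "0"))
        orders.append(order)
        for _ in range(families_per_order):
            family = _fresh_word(rng, used).capitalize() + "idae"
            fid = new_id()
            rows.append((fid, family, "family", oid))
            families.append(family)
            for _ in range(genera_per_family):
                genus = _fresh_word(rng, used).capitalize()
                gid = new_id()
                rows.append((gid, genus, "genus", fid))
                genera[genus] = []
                family_of_genus[genus] = family
                for _ in range(species_per_genus):
                    epithet = _fresh_word(rng, used, syllables=4)
                    sid = new_id()
                    species = f"{genus} {epithet}"
                    rows.append((sid, species, "species", gid))
                    genera[genus].append(species)

    if n_homonyms > len(families):
        raise ValueError("cannot plant more homonyms than families")
    homonyms: list[str] = []
    if n_homonyms:
        genus_pool = [g for g in genera if g not in set(families)]
        rng.shuffle(genus_pool)
        target_families = rng.sample(families, n_homonyms)
        renames: dict[str, str] = {}
        for fam in target_families:
            # reuse the spelling of a genus that does NOT belong to this family
            for g in genus_pool:
                if family_of_genus[g] != fam and g not in renames.values():
                    renames[fam] = g
                    homonyms.append(g)
                    break
        rows = [
            (tid, renames.get(name, name) if rank == "family" else name, rank, parent)
            for tid, name, rank, parent in rows
        ]
        families = [renames.get(f, f) for f in families]

    names_text = "".join(
        f"{tid}\t|\t{name}\t|\t\t|\tscientific name\t|\n" for tid, name, _, _ in rows
    )
    nodes_text = "".join(
        f"{tid}\t|\t{parent}\t|\t{rank}\t|\n" for tid, _, rank, parent in rows
    )
    return SyntheticTaxonomy(
        names_text=names_text,
        nodes_text=nodes_text,
        orders=orders,
        families=families,
        genera=genera,
        homonyms=sorted(homonyms),
        seed=seed,
    )


@dataclass
class CorpusKnobs:
    """Generation knobs; these fully determine a corpus given the seed."""

    mention_count: int = 2  # true-taxon mentions in title+abstract
    fidelity: str = "exact"  # exact | abbreviated | noisy
    metadata_dropout: float = 0.0  # fraction of records with zero metadata mentions
    homonym_tokens: tuple[str, ...] = ()  # ambiguous spellings planted in abstracts
    homonym_fraction: float = 0.0
    trees_per_record: tuple[int, int] = (1, 3)
    tips_per_tree: tuple[int, int] = (4, 12)

    def __post_init__(self) -> None:
        if self.fidelity not in FIDELITIES:
            raise ValueError(f"fidelity must be one of {FIDELITIES}")


@dataclass
class RecordTruth:
    doi: str
    true_name: str
    true_rank: str
    mention_count: int
    fidelity: str
    homonym_planted: bool


@dataclass
class CorpusTruth:
    seed: int
    knobs: CorpusKnobs
    records: list[RecordTruth] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "knobs": asdict(self.knobs),
            "records": [asdict(r) for r in self.records],
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def random_newick(labels: list[str], rng: random.Random) -> str:
    """Random binary topology over ``labels`` by coalescent-style joins."""
    nodes = [f"'{l}'" if (" " in l or ":" in l) else l for l in labels]
    while len(nodes) > 1:
        i, j = rng.sample(range(len(nodes)), 2)
        a, b = nodes[i], nodes[j]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


def _tip_label(species: str, fidelity: str, i: int, rng: random.Random) -> str:
    genus, epithet = species.split(" ", 1)
    if fidelity == "exact":
        return f"{genus}_{epithet}"
    if fidelity == "abbreviated":
        if rng.random() < 0.5:
            return f"{genus}_sp{i + 1}"  # genus-only abbreviation
        return f"{genus[0]}_{epithet}"  # one-letter genus
    # noisy: mangled beyond recognition
    return "".join(rng.choice("xqwkjy") for _ in range(8)) + str(i)


def generate_corpus(
    seed: int,
    taxonomy: SyntheticTaxonomy,
    n_records: int = 20,
    knobs: CorpusKnobs | None = None,
) -> tuple[list[dict], dict[str, str], CorpusTruth]:
    """Generate (publication records, tree files, truth) for ``n_records`` studies.

    Each record studies one true genus: its title/abstract embed the genus
    name ``mention_count`` times among stopword filler, and its 1-3 Newick
    tree files carry tips drawn from the genus's species under the fidelity
    model.  DOIs are unique.  Identical seeds yield identical bytes.
    """
    knobs = knobs or CorpusKnobs()
    rng = random.Random(seed)
    filler_words = sorted(load_default_stopwords())
    genera = sorted(taxonomy.genera)
    publications: list[dict] = []
    tree_files: dict[str, str] = {}
    truth = CorpusTruth(seed=seed, knobs=knobs)

    for i in range(n_records):
        genus = rng.choice(genera)
        species_pool = taxonomy.genera[genus]
        doi = f"10.9999/synth.{seed}.{i + 1}"
        dropped = rng.random() < knobs.metadata_dropout
        mentions = 0 if dropped else knobs.mention_count
        plant_homonym = bool(knobs.homonym_tokens) and rng.random() < knobs.homonym_fraction

        def filler(n: int) -> list[str]:
            return [rng.choice(filler_words) for _ in range(n)]

        title_words = filler(4)
        abstract_words = filler(30)
        if mentions:
            title_words.insert(rng.randrange(len(title_words) + 1), genus)
            for _ in range(mentions - 1):
                abstract_words.insert(rng.randrange(len(abstract_words) + 1), genus)
        if plant_homonym:
            tok = rng.choice(list(knobs.homonym_tokens))
            abstract_words.insert(rng.randrange(len(abstract_words) + 1), tok)

        n_trees = rng.randint(*knobs.trees_per_record)
        file_names: list[str] = []
        for t in range(n_trees):
            n_tips = rng.randint(*knobs.tips_per_tree)
            tips = [
                _tip_label(rng.choice(species_pool), knobs.fidelity, k, rng)
                for k in range(n_tips)
            ]
            fname = f"trees/synth_{seed}_{i + 1}_{t + 1}.nwk"
            tree_files[fname] = random_newick(tips, rng) + "\n"
            file_names.append(fname)

        publications.append(
            {
                "doi": doi,
                "title": " ".join([title_words[0].capitalize()] + title_words[1:]),
                "authors": [f"Author {i + 1}"],
                "abstract": " ".join(abstract_words),
                "journal": "Journal of Synthetic Phylogenetics",
                "pub_date": "2025-01-01",
                "source": "fixture",
                "tree_files": file_names,
            }
        )
        truth.records.append(
            RecordTruth(
                doi=doi,
                true_name=genus,
                true_rank="genus",
                mention_count=mentions,
                fidelity=knobs.fidelity,
                homonym_planted=plant_homonym,
            )
        )
    return publications, tree_files, truth


def write_corpus(
    directory: str | Path,
    taxonomy: SyntheticTaxonomy,
    publications: list[dict],
    tree_files: dict[str, str],
    truth: CorpusTruth,
) -> Path:
    """Materialize a generated corpus in the on-disk layout the CLI consumes."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    taxonomy.write(d)
    (d / "publications.json").write_text(
        json.dumps(publications, sort_keys=True, indent=1), "utf-8"
    )
    for rel, content in tree_files.items():
        path = d / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(content, "utf-8")
    (d / "truth.json").write_text(truth.to_json(), "utf-8")
    return d
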