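# Methods

## Problem and pipeline

Published phylogenetic trees are scattered across repository deposits as
Newick or NEXUS files, often inside nested archives, and the taxon a study
covers is stated only informally in its title and abstract. The toolkit
standardizes five stages: (1) harvest/bibliographic intake keyed by DOI,
(2) tree-file discovery and validation, (3) taxonomic assignment by two
independent methods, (4) reconciliation into a single study-level name with
a confidence class, (5) export to a JSON + Newick-archive dataset and a
six-table relational projection.

## Taxonomy index

The reference taxonomy is read in the NCBI-taxdump dialect (`names.dmp` /
`nodes.dmp`, fields separated by `\t|\t`) or a single-file TSV with an
explicit rank column. Only rows whose name class is "scientific name" are
indexed; synonyms and common names are ignored — an open choice, since
indexing synonyms would raise recall at the cost of many more homonym
collisions. Exactly four ranks are kept: order, family, genus, species.
Matching is case-insensitive with canonical capitalization stored (genus,
family and order capitalized, species epithets lowercased), because titles
capitalize freely and tip labels vary. Every spelling claimed by two or
more taxon ids is kept in a homonym map so downstream candidates can be
flagged ambiguous. Parsing is tolerant by default (malformed rows are
counted and skipped); a strict flag turns them into errors.

## Metadata candidate (Name1)

Tokens are maximal runs of letters/digits with internal hyphens kept; the
token bag is augmented with binomial pairs (capitalized word + lowercase
word). A binomial whose epithet is a common English word or a simple
inflection of one ("occurs", "changed") is rejected: a capitalized genus
followed by ordinary prose is almost never a species name. The 1000 most
common English words are then removed (case-insensitively; binomials are
protected) and the survivors intersected with the four rank sets.

When several names match, one must be chosen. Selection is by raw
occurrence frequency in the title+abstract stream, tie-broken broader rank
first (order > family > genus > species) and then lexicographically — the
study-level taxon is the target, so the broader reading is preferred on
ties; all runners-up are preserved as alternatives. A candidate is flagged
ambiguous when its spelling is a homonym in the index or when another name
ties its frequency. This deliberately reproduces the known failure mode
where *Mya* in a paper about divergence times ("5 Mya") is read as the clam
genus: flagging, not suppression, is the designed behavior, since the same
string is a legitimate genus mention elsewhere.

The bundled stopword list (`data/stopwords.txt`, one word per line, UTF-8)
is the package's own snapshot of 1000 high-frequency English words; a
user-supplied list can be passed instead. Digits-only tokens never reach
the intersection.

## Tree candidate (Name2)

Discovery expands ZIP/TAR/GZ archives recursively to depth 3 (corrupt
archives and deeper nesting are skipped with warnings), then keeps files
whose suffix — compared case-insensitively — is one of `.nwk`, `.newick`,
`.nex`, `.nexus`, `.tre`, `.tree`, `.treefile`, `.txt`. A `.txt` file
counts only if it actually parses. Validation tries Newick then NEXUS
(TRANSLATE tables resolved) via DendroPy, decoding UTF-8 with a Latin-1
fallback; a valid file has ≥1 tree and every tree ≥2 tips. Duplicate tip
labels are legal and counted as a multiset (the parser falls back to
label-only reading when a file repeats a label). Underscores in unquoted
labels are preserved verbatim rather than read as spaces, since sample
labels use them as separators, not Newick escapes.

Tip labels are normalized into up to three lookup candidates: the cleaned
full string, the leading two-word binomial, and the leading genus word,
after replacing underscores/pipes with spaces, stripping quotes, and
dropping trailing accession-like tokens (all-digit or uppercase+digit). A
matched species also increments its genus count, because abbreviated labels
usually resolve only to genus. Matches are pooled across all of a study's
files and the maximal-frequency name selected with the same tie-break as
Name1.

A credibility floor guards against single stray matches: the top candidate
must occur ≥2 times or cover ≥10% of pooled tips (both tunable). One
matching tip among hundreds is weak evidence; in a small tree it is
proportionally meaningful. The floor is what turns "no credible name" into
an absent Name2.

## Reconciliation

Equality for the agreement rule is name+rank equality after canonical
capitalization — a species Name2 under a genus Name1 counts as *different*
(Name1 wins) but earns a `consistent-lineage` note when parent links show
the nesting. The four confidence classes (`both_agree`, `metadata_only`,
`tree_only`, `undetermined`) map one-to-one onto the validation strata used
for accuracy audits. The known under-assignment mode — a class-wide study
whose tips are dominated by one genus getting that genus as a tree-only
name — is reproduced by design and left uncorrected; resolving it requires
information outside the tip labels.

## Records and export

DOIs are canonicalized (resolver prefix stripped, lowercased, must start
`10.`) and used as the dedup key; the first record per DOI is kept in
stable order and later duplicates merge field-wise into absent fields only,
so metadata completed from a secondary source is not lost. Tree IDs are
deterministic `{doi-slug}.{ordinal}` strings so re-runs are reproducible.
`Paper.json` is a sorted-key UTF-8 JSON array; the archive holds exactly
one Newick member per referenced tree ID, and export/import round-trips
losslessly. The relational projection emits six tables (Study, Tree,
TreeFile, Taxonomy, Matrix, Submit) joined one-to-one by synthetic primary
keys; Matrix is an empty placeholder because alignment harvesting is out of
scope, and Submit carries harvest timestamp and pipeline version.

## API clients

Repository and metadata clients are pure functions of an injected transport
callable, so every behavior is testable offline by replaying recorded
responses keyed by a request hash. Downloadability predicates: a Dryad hit
needs a non-empty identifier and a storage size; a FigShare hit needs a
non-empty files list. Crossref-style payloads fill absent bibliographic
fields only. Live crawling is out of scope; the keyword query builder
("phylogeny", "phylogenetics", "evolution", "systematics") is exposed for
callers that plug in an HTTP transport. Node-link dumps (the storage model
of legacy tree databases) are reconstructed into Newick with children
ordered by their smallest descendant leaf label, making output
deterministic; cycles, disconnection, multiple parents and unlabeled
leaves raise typed errors.

## Synthetic corpora

The generator emulates the pipeline's inputs with planted truth. A
taxonomy is built from pronounceable random names with exact requested
counts; cross-rank homonyms are planted by renaming families to genus
spellings. Each corpus record studies one true genus: its title/abstract
embed the genus name a configured number of times among stopword filler
(so stopword removal is exercised), and 1–3 Newick files carry 4–12 tips
drawn from the genus's species under a fidelity model — `exact`
(`Genus_epithet`), `abbreviated` (a mix of `Genus_spN` and one-letter
`G_epithet`), `noisy` (mangled strings). Knobs add metadata dropout
(records with zero mentions, making tree evidence decisive) and planted
ambiguous tokens. Topologies are random coalescent-style joins; topology
is irrelevant to assignment, only labels matter. Everything is a pure
function of the seed — identical seeds give identical bytes.

What the simulator does not model: real abstract language statistics,
multi-kingdom studies, simulated-tree papers, OCR noise, or taxonomies with
synonyms. Passing tests therefore demonstrate the mechanics of the
pipeline and its documented failure modes, not field accuracy on real
literature, where metadata-only assignments are known to be imperfect.

## Default problem sizes

Default audits use a 3-order × 3-family × 4-genus × 5-species taxonomy
(180 species), 200-record corpora for stratified accuracy, 60 records per
fidelity level, 1000 random trees for parser round-trips and 200 for
node-link reconstruction — large enough for stable percentages while a
full audit completes in seconds.

## Known limitations

- Name1 selection by raw frequency is a design choice; other rules
  (rank-priority-first, title-weighted) are plausible and would shift
  ambiguous cases.
- Genus-level homonyms across kingdoms are flagged, not resolved.
- NEXUS support covers TREES blocks with TRANSLATE tables; exotic blocks
  are ignored.
- The credibility floor trades recall for precision and is deliberately
  conservative at its defaults.
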