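# Methods

## The curation model

termorg models collaborative controlled-vocabulary building over terms
extracted from descriptive literature (morphological descriptions of
plants, insects, sponges, fossils, ...).  A *workspace* holds users,
datasets, reference glossaries, and a global concept dictionary.  Each
dataset is scoped to a taxon group and carries up to one *term set* per
organization task:

- **grouping** — is_a categorization: each curator places terms into
  categories, may copy a term into several categories when it is a
  homonym (*sweet* as a taste vs. as a smell), and may link synonyms onto
  a preferred term within a category.
- **hierarchy** — part_of placement: each curator edits a private copy of
  a shared default tree; saving turns new nodes into root-to-term path
  decisions.  A term may label several nodes (many structures have a
  *base*).
- **ordering** — ranked categorical states: named orders over term
  groups, where a box holds one or more tied terms and a term's distance
  is its box index counted from zero.

Decisions are per-user, timestamped, and append-only.  Re-assignment
supersedes a user's current decision but never deletes history, so a
term's complete decision trail is always reconstructible.  The *working
view* shows, per term, the decision set of the user whose latest decision
is newest; equal timestamps break by username so the view is a pure,
deterministic function of the history.

### Conflict detection

A grouping term is conflicted when at least two users hold non-identical
decision signatures for it, a signature being the pair (set of current
categories, set of active synonym links touching the term).  Synonym
links are part of the signature because synonymizing is part of the
categorization decision surface and is adjudicated at the same review
step.  Hierarchy conflicts compare users' *sets* of saved paths per term
(identical multi-placement is not a conflict); ordering conflicts compare
saved box sequences of same-named orders (box order and tie membership
both matter).  All three detectors are verified against exhaustive
pairwise brute-force oracles on randomized sessions.

The conflict statistic counts a categorization record as "in conflict"
when its term is conflicted, over *all* records ever made (superseded
ones included), since campaign-level totals count decisions made rather
than surviving ones.  The conflict rate is
`100 × conflict_categorizations / categorizations`, rounded to one
decimal, and 0 when no categorizations exist.

### Finalization, concepts, versions

Reviewing partitions distinct decisions into accepted vs. other, with
supporter sets.  Finalizing freezes the term set, increments the minor
version by exactly 1 (rendered `v{major}.{minor}`), and releases only
accepted decisions; everything else is retained in the store.  Every
accepted ⟨term, category⟩ is bound — through the workspace-global,
append-only dictionary — to a permanent random version-4 UUID.  The
dictionary lives outside any dataset, so deleting a dataset, reopening,
re-finalizing, or merging can never re-mint or orphan an identifier.
Synonym terms never receive standalone glossary rows; their rows in the
syns file carry the preferred pair's UUID.

### Merging

*Merge unfinalized* unions open datasets of one taxon group: duplicate
normalized terms collapse with source sentences and documents unioned,
and decisions carry over with original authors and timestamps so the
working view and conflict flags are stable under merge.  Sources are
deleted only after the merged workspace is durably saved (write-then-
delete with an atomic file rename).  Exact-duplicate
(document, sentence) pairs collapse — sentence identity, like term
identity, is exact-match.  *Merge into system* folds finalized released
content into the admin-managed `<TaxonGroup>_glossary` dataset,
deduplicates by concept triple (existing UUIDs win), and automatically
re-finalizes it with a bumped version.

## Normalization and identity

A term's identity key is its surface form lower-cased with surrounding
whitespace stripped; internal hyphens and spaces are preserved.
Aggressive stemming would merge morphologically distinct terms
(*toothed* vs. *tooth*), while case variants (*Leaf*/*leaf*) are the same
term.  Hierarchy paths are stored as ordered term lists; the
hyphen-joined rendering (`plant-flower-stamen-anther`) is derived output
only and never parsed back, because terms themselves may contain hyphens.
Sibling order in trees is insertion order for display but ignored by
equality and conflict detection — part_of semantics is order-free.

## Time

All timestamps come from an injectable clock.  The default is the system
clock; `TickClock` yields a strictly increasing deterministic sequence
(1 s steps from 2000-01-01T00:00:00Z) and persists its tick count with
the workspace, which makes replays, tests, and released files
byte-reproducible.  Ties across users at identical instants are broken
lexicographically by username.

## File formats

Released grouping glossaries are two CSV files (RFC 4180, UTF-8, LF,
header row): `<dataset>_term_category.csv`
(`term, category, hasSyn, sourceDataset, termID`) and `<dataset>_syns.csv`
(`term, category, termID, synonym`), both opening with `*`-prefixed
metadata comments (version, release date, participants) and the former
closing with `*`-prefixed category definitions.  Data rows sort by
(category, term); multi-document `sourceDataset` values join with `"; "`.
The reader cross-validates the pair (hasSyn consistency, no duplicate or
synonym-leaked rows, well-formed UUIDs) and write∘read∘write is
byte-identical.  Ordering and hierarchy releases export as single tables
with columns `orderID, orderName, term, distance, accepted, userid,
confirmDate` and `term, pathWithName, accepted, userid, confirmDate`;
only accepted rows are exported, so `accepted` is always 1, and
`confirmDate` is ISO-8601.  Category names must not contain `": "` (the
definition-line separator); unplaced group members are omitted from
order serialization.

Import bundles are a directory with a `manifest.txt` (`key: value`) and
optional per-task CSV/text files; see
`termorg.glossary_io.ImportBundle`.

## The synthetic-data generator

`termorg.fixtures` emulates a multi-user campaign: user 1 assigns every
term a base category drawn uniformly from the category inventory; each
further user independently deviates to a different category with
probability *p* (`disagreement_prob`); synonym and homonym copy events
are injected at their own rates, always by user 1.  For *k* users the
conflicted-term fraction is therefore `1 − (1 − p)^(k−1)` in expectation,
which the statistical tests recover within three binomial standard
errors.  Defaults (200 terms, 3 users, 8 categories, p = 0.3,
synonym/homonym rates 0.05) describe a small but realistically
contentious session; identical spec + seed reproduces the bundle and
script byte-for-byte.

What the generator does *not* emulate: correlated disagreement between
curators (real conflicts cluster on genuinely ambiguous terms), category
inventories that grow mid-campaign, terms whose surface forms collide
under normalization, and linguistic structure in sentences.  Passing
tests therefore demonstrate the bookkeeping — histories, conflicts,
releases, identifiers — not that the engine resolves the semantics of
real terminology.

## Problem sizes and numerical choices

Tests run the conflict-oracle suites on 200+ randomized sessions per
detector at ≤ 10 users × ≤ 50 terms, and the statistical recovery at
2000 terms × 2 users — sizes at which binomial sampling error (±3 SE ≈
±0.031 at p = 0.3) is tight enough to detect systematic bias while the
whole suite stays interactive.  The acceptance script uses the same
sizes.  Degenerate inputs are defined rather than special-cased: empty
term lists are an import error, an empty default hierarchy falls back to
a single root named after the taxon group, conflict rate at zero
categorizations is 0, and finalizing with nothing accepted is an error.

## Known limitations

- One term set per task per dataset; no per-term-set ownership distinct
  from the dataset owner, and ownership transfer is unsupported.
- Synonym links are within-category stars; chains and cross-category
  links are rejected rather than normalized.
- The JSON store loads fully into memory; it is desk-scale (up to tens
  of thousands of terms), not server-scale.
- Reference glossaries stand in for live external vocabulary lookups;
  there is no HTTP layer.
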