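# termorg

A headless, scriptable engine for **collaborative curation of domain
terminology**: several curators organize terms extracted from descriptive
literature into *is_a* categories with synonym sets, *part_of*
hierarchies, and ordered categorical series, while the engine tracks
every per-user decision, flags cross-user conflicts, merges datasets, and
releases versioned glossary files whose concepts carry permanent UUIDs.

It is built for biodiversity informatics — taxonomic descriptions use
terms like *leaf*, *alternate*, or *glabrous* whose semantics
(leaf **is_a** structure, alternate **is_a** arrangement, stipule
**part_of** leaf, glabrous < pilose < tomentose on a hairiness scale) must
be made explicit before morphological text can feed matrices, reasoning,
or ontology building — but works for any domain needing is_a / part_of /
order semantics over a term inventory.

## The model in brief

- A **workspace** holds users, datasets (scoped to a taxon group such as
  Plant or Hymenoptera), reference glossaries, and a global, append-only
  **concept dictionary** mapping each ⟨term, category, taxon group⟩
  triple to a permanent version-4 UUID.
- A dataset has up to one **term set** per task (grouping, hierarchy,
  ordering).  Decisions are per-user and timestamped; superseded
  decisions stay in the history.  The working view always shows the most
  recent decision across users.
- A term is **conflicted** when two users hold non-identical decision
  signatures for it — category sets plus synonym links for grouping,
  saved path sets for hierarchies, box sequences for orders.  The
  conflict rate of a campaign is
  `100 × conflict_categorizations / categorizations`.
- **Finalizing** freezes a term set, bumps its version (`v0.1`, `v0.2`,
  ...), registers UUIDs for every accepted ⟨term, category⟩, and releases
  only accepted decisions as CSV glossary files.  Reopening, re-finalizing,
  deleting, and merging never change an existing UUID.
- Orders serialize one row per term with an integer **distance** — the
  term's box index counted from zero, so tied terms share a distance and
  an order of N terms yields exactly N rows.

## Worked example

The telegraphic description *"Leaves alternate, spirally arranged,
simple; stipules deciduous, distinct; petioles present."* yields the
terms `leaf`, `alternate`, `stipule`, `petiole`.  Organize, approve,
finalize, and export them:

```sh
termorg --store ws init --deterministic-clock
termorg --store ws user add alice
termorg --store ws import bundle/        # manifest + term lists + defaults
termorg --store ws group assign leaf      --dataset Betulaceae --user alice --category structure
termorg --store ws group assign alternate --dataset Betulaceae --user alice --category arrangement
termorg --store ws hier add stipule --dataset Betulaceae --user alice --parent plant/leaf
termorg --store ws hier add petiole --dataset Betulaceae --user alice --parent plant/leaf
termorg --store ws hier save --dataset Betulaceae --user alice
termorg --store ws review approve '["cat","leaf","structure"]'      --dataset Betulaceae --user alice
termorg --store ws review approve '["cat","alternate","arrangement"]' --dataset Betulaceae --user alice
termorg --store ws review approve '["path","stipule","plant","leaf","stipule"]' --dataset Betulaceae --task hierarchy --user alice
termorg --store ws review approve '["path","petiole","plant","leaf","petiole"]' --dataset Betulaceae --task hierarchy --user alice
termorg --store ws finalize --dataset Betulaceae --user alice
termorg --store ws finalize --dataset Betulaceae --task hierarchy --user alice
termorg --store ws export --dataset Betulaceae --out out/
```

`out/Betulaceae_term_category.csv` then contains the two released is_a
concepts, each bound to its permanent UUID, between the metadata comment
block and the trailing category definitions:

```
* glossary: Betulaceae
* version: v0.1
* release_date: 2000-01-01T00:00:04+00:00
* participants: alice
term,category,hasSyn,sourceDataset,termID
alternate,arrangement,0,,a9cb03c0-8f98-4d6b-ae89-3ff371b4d208
leaf,structure,0,,97d51a71-da0d-451f-8f03-004e75289bf5
* category: arrangement: How organs are positioned.
* category: structure: A plant organ or part.
```

(`hasSyn` is 0 because no synonyms were linked; the companion
`Betulaceae_syns.csv` is correspondingly empty of data rows.)  The two
part_of placements land in `out/Betulaceae_paths_table.csv` as
hyphen-joined root-to-term paths:

```
term,pathWithName,accepted,userid,confirmDate
petiole,plant-leaf-petiole,1,alice,2000-01-01T00:00:03+00:00
stipule,plant-leaf-stipule,1,alice,2000-01-01T00:00:02+00:00
```

and `termorg --store ws stats --dataset Betulaceae --json` reports the
campaign counters — 4 unique terms, 2 categorizations by 1 user, 2
released concepts, conflict rate 0.0 since there was a single curator.

The same pipeline is available as a library (`termorg.Workspace`,
`termorg.grouping`, `termorg.hierarchy`, `termorg.ordering`,
`termorg.lifecycle`, `termorg.glossary_io`), and
`termorg.fixtures.FixtureSpec` generates deterministic multi-user
sessions for experiments — e.g. two curators disagreeing independently
with probability 0.3 conflict on ≈30% of terms
(`1 − (1 − p)^(k−1)` in expectation).

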