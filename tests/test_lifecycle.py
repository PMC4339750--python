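"""Review, finalization, reopening, merging, and statistics."""
import random

import pytest

from termorg import Workspace, grouping, hierarchy, lifecycle, ordering
from termorg.clock import TickClock
from termorg.errors import (FrozenTermSetError, InvalidOperation,
                            PermissionDenied)
from termorg.model import ReferenceGlossary, Term

from conftest import random_grouping_session


class TestReviewAndApproval:
    def test_shared_decision_has_all_supporters(self, ws, demo):
        _, ts = demo
        for user in ("alice", "bob", "carol"):
            grouping.assign(ws, ts, user, ["leaf"], "structure")
        decisions = lifecycle.review(ws, "alice", ts)
        (d,) = [d for d in decisions if d["key"] == ("cat", "leaf", "structure")]
        assert d["supporters"] == ["alice", "bob", "carol"]

    def test_competing_decisions_have_disjoint_supporters(self, ws, demo):
        _, ts = demo
        grouping.assign(ws, ts, "alice", ["leaf"], "structure")
        grouping.assign(ws, ts, "bob", ["leaf"], "arrangement")
        decisions = {d["key"]: d["supporters"]
                     for d in lifecycle.review(ws, "alice", ts)}
        assert decisions[("cat", "leaf", "structure")] == ["alice"]
        assert decisions[("cat", "leaf", "arrangement")] == ["bob"]

    def test_review_requires_owner_or_admin(self, ws, demo):
        _, ts = demo
        grouping.assign(ws, ts, "alice", ["leaf"], "structure")
        with pytest.raises(PermissionDenied):
            lifecycle.review(ws, "bob", ts)
        lifecycle.review(ws, "root", ts)   # admin may

    def test_approve_reject_toggle(self, ws, demo):
        _, ts = demo
        grouping.assign(ws, ts, "alice", ["leaf"], "structure")
        grouping.assign(ws, ts, "bob", ["leaf"], "arrangement")
        lifecycle.approve(ws, "alice", ts, ("cat", "leaf", "structure"))
        accepted = [d for d in lifecycle.review(ws, "alice", ts) if d["accepted"]]
        assert [d["key"] for d in accepted] == [("cat", "leaf", "structure")]
        lifecycle.reject(ws, "alice", ts, ("cat", "leaf", "structure"))
        assert not any(d["accepted"] for d in lifecycle.review(ws, "alice", ts))

    def test_multi_category_approval_permitted(self, ws, demo):
        _, ts = demo
        grouping.assign(ws, ts, "alice", ["leaf"], "structure")
        grouping.copy_assign(ws, ts, "alice", "leaf", "arrangement")
        lifecycle.approve(ws, "alice", ts, ("cat", "leaf", "structure"))
        lifecycle.approve(ws, "alice", ts, ("cat", "leaf", "arrangement"))
        version = lifecycle.finalize(ws, "alice", ts)
        assert len(version.content["concepts"]) == 2
        assert lifecycle.stats(ts).multi_category_terms == 1

    def test_approve_all_system_counts_new_matches_only(self, ws, demo):
        _, ts = demo
        ref = ReferenceGlossary("ref", "Plant", {
            "leaf": [("structure", None)], "alternate": [("arrangement", None)]})
        grouping.assign(ws, ts, "alice", ["leaf"], "structure")
        grouping.assign(ws, ts, "alice", ["alternate"], "arrangement")
        grouping.assign(ws, ts, "alice", ["stipule"], "structure")
        assert lifecycle.approve_all_system(ws, "alice", ts, ref) == 2
        assert lifecycle.approve_all_system(ws, "alice", ts, ref) == 0
        accepted = {d["key"] for d in lifecycle.review(ws, "alice", ts)
                    if d["accepted"]}
        assert accepted == {("cat", "leaf", "structure"),
                            ("cat", "alternate", "arrangement")}

    def test_empty_reference_approves_nothing(self, ws, demo):
        _, ts = demo
        grouping.assign(ws, ts, "alice", ["leaf"], "structure")
        ref = ReferenceGlossary("ref", "Plant", {})
        assert lifecycle.approve_all_system(ws, "alice", ts, ref) == 0


class TestFinalizeReopen:
    def test_only_accepted_decisions_enter_content(self, ws, demo):
        _, ts = demo
        grouping.assign(ws, ts, "alice", ["leaf", "alternate", "stipule"],
                        "structure")
        for term in ("leaf", "alternate"):
            lifecycle.approve(ws, "alice", ts, ("cat", term, "structure"))
        version = lifecycle.finalize(ws, "alice", ts)
        assert {c["term"] for c in version.content["concepts"]} == \
               {"leaf", "alternate"}
        # unaccepted decisions are retained in the store, just not released
        assert any(r.term == "stipule" for r in ts.data.records)

    def test_finalize_requires_accepted_decision(self, ws, demo):
        _, ts = demo
        grouping.assign(ws, ts, "alice", ["leaf"], "structure")
        with pytest.raises(InvalidOperation):
            lifecycle.finalize(ws, "alice", ts)

    def test_version_walk_and_uuid_permanence(self, ws, demo):
        _, ts = demo
        grouping.assign(ws, ts, "alice", ["leaf"], "structure")
        lifecycle.approve(ws, "alice", ts, ("cat", "leaf", "structure"))
        v1 = lifecycle.finalize(ws, "alice", ts)
        assert v1.version == (0, 1)
        lifecycle.reopen(ws, "alice", ts)
        grouping.assign(ws, ts, "alice", ["alternate"], "arrangement")
        lifecycle.approve(ws, "alice", ts, ("cat", "alternate", "arrangement"))
        v2 = lifecycle.finalize(ws, "alice", ts)
        assert v2.version == (0, 2)
        uuid_of = lambda v: {c["term"]: c["uuid"] for c in v.content["concepts"]}
        assert uuid_of(v1)["leaf"] == uuid_of(v2)["leaf"]
        # earlier releases stay immutable and retrievable
        assert ts.versions[0] is v1 and v1.version == (0, 1)

    def test_reopen_then_edit(self, ws, demo):
        _, ts = demo
        grouping.assign(ws, ts, "alice", ["leaf"], "structure")
        lifecycle.approve(ws, "alice", ts, ("cat", "leaf", "structure"))
        lifecycle.finalize(ws, "alice", ts)
        with pytest.raises(FrozenTermSetError):
            grouping.assign(ws, ts, "alice", ["stipule"], "structure")
        lifecycle.reopen(ws, "alice", ts)
        grouping.assign(ws, ts, "alice", ["stipule"], "structure")
        with pytest.raises(InvalidOperation):
            lifecycle.reopen(ws, "alice", ts)

    def test_synonym_terms_excluded_from_concepts(self, ws, demo):
        _, ts = demo
        grouping.assign(ws, ts, "alice", ["leaf", "stipule"], "structure")
        grouping.synonymize(ws, ts, "alice", "stipule", "leaf")
        lifecycle.approve(ws, "alice", ts, ("cat", "leaf", "structure"))
        lifecycle.approve(ws, "alice", ts, ("syn", "leaf", "stipule", "structure"))
        version = lifecycle.finalize(ws, "alice", ts)
        assert [c["term"] for c in version.content["concepts"]] == ["leaf"]
        assert version.content["concepts"][0]["has_syn"] is True
        (s,) = version.content["synonyms"]
        assert s["synonym"] == "stipule"
        assert s["uuid"] == version.content["concepts"][0]["uuid"]

    @pytest.mark.parametrize("seed", range(10))
    def test_finalized_content_equals_accepted_set(self, seed):
        """Exhaustive diff between random accepted subsets and the release."""
        rng = random.Random(seed)
        ws = Workspace(clock=TickClock())
        _, ts = random_grouping_session(ws, n_users=3, n_terms=25, seed=seed)
        decisions = [d["key"] for d in lifecycle.review(ws, "owner", ts)]
        chosen = {k for k in decisions if rng.random() < 0.5 and k[0] == "cat"}
        for key in chosen:
            lifecycle.approve(ws, "owner", ts, key)
        if not chosen:
            with pytest.raises(InvalidOperation):
                lifecycle.finalize(ws, "owner", ts)
            return
        version = lifecycle.finalize(ws, "owner", ts)
        released = {("cat", c["term"], c["category"])
                    for c in version.content["concepts"]}
        assert released == chosen


class TestMergeUnfinalized:
    def _dataset(self, ws, name, terms_with_sentences, owner="alice"):
        ds = ws.create_dataset(name, "Plant", owner)
        terms = [Term(t, t, sents) for t, sents in terms_with_sentences]
        ws.import_term_set(ds, "grouping", terms,
                           default_categories=["structure"])
        return ds

    def test_terms_dedup_and_sentences_union(self, ws):
        self._dataset(ws, "A", [("base", [("fna_v3", "Base truncate.")]),
                                ("leaf", [("fna_v3", "Leaves alternate.")])])
        self._dataset(ws, "B", [("base", [("foc_v4", "Base rounded.")])])
        merged = lifecycle.merge_unfinalized(ws, "alice", ["A", "B"], "AB")
        ts = merged.term_sets["grouping"]
        assert set(ts.terms) == {"base", "leaf"}
        assert set(ts.terms["base"].source_sentences) == {
            ("fna_v3", "Base truncate."), ("foc_v4", "Base rounded.")}
        assert "A" not in ws.datasets and "B" not in ws.datasets
        assert merged.merged_from == ["A", "B"]

    def test_decisions_carry_attribution_and_timestamps(self, ws):
        a = self._dataset(ws, "A", [("base", [])])
        b = self._dataset(ws, "B", [("base", []), ("leaf", [])])
        grouping.assign(ws, a.term_sets["grouping"], "bob", ["base"], "structure")
        stamp = a.term_sets["grouping"].data.records[0].timestamp
        merged = lifecycle.merge_unfinalized(ws, "alice", ["A", "B"], "AB")
        (rec,) = merged.term_sets["grouping"].data.records
        assert (rec.user, rec.timestamp) == ("bob", stamp)

    def test_mixed_taxon_groups_rejected(self, ws):
        self._dataset(ws, "A", [("base", [])])
        ds = ws.create_dataset("H", "Hymenoptera", "alice")
        ws.import_term_set(ds, "grouping", ["gaster"])
        with pytest.raises(InvalidOperation):
            lifecycle.merge_unfinalized(ws, "alice", ["A", "H"], "AH")

    def test_finalized_source_rejected(self, ws):
        a = self._dataset(ws, "A", [("base", [])])
        self._dataset(ws, "B", [("leaf", [])])
        ts = a.term_sets["grouping"]
        grouping.assign(ws, ts, "alice", ["base"], "structure")
        lifecycle.approve(ws, "alice", ts, ("cat", "base", "structure"))
        lifecycle.finalize(ws, "alice", ts)
        with pytest.raises(InvalidOperation):
            lifecycle.merge_unfinalized(ws, "alice", ["A", "B"], "AB")

    def test_non_owner_cannot_merge(self, ws):
        self._dataset(ws, "A", [("base", [])])
        self._dataset(ws, "B", [("leaf", [])])
        with pytest.raises(PermissionDenied):
            lifecycle.merge_unfinalized(ws, "bob", ["A", "B"], "AB")

    def test_atomic_swap_persists_before_source_deletion(self, ws, tmp_path):
        ws.save(tmp_path / "w")
        self._dataset(ws, "A", [("base", [])])
        self._dataset(ws, "B", [("leaf", [])])
        lifecycle.merge_unfinalized(ws, "alice", ["A", "B"], "AB")
        reloaded = Workspace.load(tmp_path / "w")
        assert set(reloaded.datasets) == {"AB"}

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_conserves_term_union_and_sentence_multiset(self, seed):
        rng = random.Random(seed)
        ws = Workspace(clock=TickClock())
        ws.add_user("alice")
        names, all_terms, all_sentences = [], set(), []
        for i in range(3):
            name = f"D{i}"
            names.append(name)
            terms = []
            for j in range(rng.randint(2, 8)):
                t = f"t{rng.randint(0, 12)}"
                sent = (f"vol{i}", f"sentence {i}.{j} mentions {t}")
                terms.append((t, [sent]))
                all_terms.add(t)
                all_sentences.append(sent)
            self._dataset(ws, name, terms)
        merged = lifecycle.merge_unfinalized(ws, "alice", names, "M")
        ts = merged.term_sets["grouping"]
        assert set(ts.terms) == all_terms
        got = sorted(s for t in ts.terms.values() for s in t.source_sentences)
        assert got == sorted(all_sentences)


class TestMergeIntoSystem:
    def _finalized(self, ws, name, pairs, owner="alice"):
        ds = ws.create_dataset(name, "Plant", owner)
        ts = ws.import_term_set(ds, "grouping", [t for t, _ in pairs],
                                default_categories=sorted({c for _, c in pairs}))
        for term, cat in pairs:
            grouping.assign(ws, ts, owner, [term], cat)
            lifecycle.approve(ws, owner, ts, ("cat", term, cat))
        lifecycle.finalize(ws, owner, ts)
        return ds

    def test_merge_bumps_system_version_with_union(self, ws):
        ws.create_dataset("Plant_glossary", "Plant", "root", "system_reserved")
        self._finalized(ws, "A", [("leaf", "structure"), ("base", "structure"),
                                  ("alternate", "arrangement")])
        version = lifecycle.merge_into_system(ws, "root", ["A"], "Plant_glossary")
        assert version.version == (0, 1)
        assert len(version.content["concepts"]) == 3
        assert "A" not in ws.datasets
        sys_ts = ws.datasets["Plant_glossary"].term_sets["grouping"]
        assert not sys_ts.is_open

    def test_overlapping_triple_keeps_original_uuid(self, ws):
        ws.create_dataset("Plant_glossary", "Plant", "root", "system_reserved")
        original = ws.register_concept("leaf", "structure", "Plant").uuid
        self._finalized(ws, "A", [("leaf", "structure")])
        version = lifecycle.merge_into_system(ws, "root", ["A"], "Plant_glossary")
        (c,) = version.content["concepts"]
        assert c["uuid"] == original
        assert len([r for r in ws.concepts.values()
                    if r.triple == ("leaf", "structure", "Plant")]) == 1

    def test_second_merge_deduplicates_concepts(self, ws):
        ws.create_dataset("Plant_glossary", "Plant", "root", "system_reserved")
        self._finalized(ws, "A", [("leaf", "structure")])
        lifecycle.merge_into_system(ws, "root", ["A"], "Plant_glossary")
        self._finalized(ws, "B", [("leaf", "structure"), ("base", "structure")])
        v2 = lifecycle.merge_into_system(ws, "root", ["B"], "Plant_glossary")
        assert v2.version == (0, 2)
        assert len(v2.content["concepts"]) == 2

    def test_non_admin_and_unfinalized_source_rejected(self, ws):
        ws.create_dataset("Plant_glossary", "Plant", "root", "system_reserved")
        self._finalized(ws, "A", [("leaf", "structure")])
        with pytest.raises(PermissionDenied):
            lifecycle.merge_into_system(ws, "alice", ["A"], "Plant_glossary")
        ds = ws.create_dataset("B", "Plant", "alice")
        ws.import_term_set(ds, "grouping", ["base"])
        with pytest.raises(InvalidOperation):
            lifecycle.merge_into_system(ws, "root", ["B"], "Plant_glossary")

    def test_uuid_stability_under_random_replay(self, ws):
        """Finalize/reopen/merge sequences never re-mint a known triple."""
        ws.create_dataset("Plant_glossary", "Plant", "root", "system_reserved")
        rng = random.Random(7)
        snapshots = {}
        for i in range(4):
            pairs = [(f"t{rng.randint(0, 5)}", "structure") for _ in range(3)]
            self._finalized(ws, f"S{i}", sorted(set(pairs)))
            lifecycle.merge_into_system(ws, "root", [f"S{i}"], "Plant_glossary")
            for triple, rec in ws.concepts.items():
                assert snapshots.setdefault(triple, rec.uuid) == rec.uuid
            sys_ts = ws.datasets["Plant_glossary"].term_sets["grouping"]
            versions = [v.version for v in sys_ts.versions]
            assert versions == sorted(set(versions))


class TestStats:
    def test_printed_count_arithmetic(self):
        assert lifecycle.conflict_rate_percent(5295, 11781) == 44.9

    def test_empty_term_set_all_zero(self, ws, demo):
        _, ts = demo
        s = lifecycle.stats(ts)
        assert (s.categorizations, s.conflict_categorizations,
                s.conflict_rate, s.users, s.comments) == (0, 0, 0.0, 0, 0)
        assert s.unique_terms == 4

    def test_known_construction_matches_oracle(self, ws, demo):
        """2 users, 4 terms, disagreement on 2: conflict records counted on
        conflicted terms only."""
        _, ts = demo
        for term in ("leaf", "alternate", "stipule", "petiole"):
            grouping.assign(ws, ts, "alice", [term], "structure")
        for term, cat in (("leaf", "structure"), ("alternate", "arrangement"),
                          ("stipule", "arrangement"), ("petiole", "structure")):
            grouping.assign(ws, ts, "bob", [term], cat)
        s = lifecycle.stats(ts)
        assert s.categorizations == 8
        assert s.conflict_categorizations == 4   # 2 conflicted terms x 2 records
        assert s.conflict_rate == 50.0
        assert s.users == 2

    def test_agrees_with_grouping_conflicts_on_random_sessions(self):
        ws = Workspace(clock=TickClock())
        _, ts = random_grouping_session(ws, n_users=4, n_terms=30, seed=11)
        conflicted = grouping.detect_conflicts(ts)
        expected = sum(1 for r in ts.data.records if r.term in conflicted)
        assert lifecycle.stats(ts).conflict_categorizations == expected
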