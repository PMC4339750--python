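"""Review, finalization, merging, and curation statistics.

Finalization is the act that turns a pile of per-user decisions into a
released glossary: the owner (or an administrator) approves individual
decisions, presses finalize, and the engine freezes the term set, bumps
the minor version, mints or reuses permanent concept UUIDs for every
accepted ⟨term, category⟩ pair, and records an immutable
:class:`~termorg.model.GlossaryVersion`.  Unaccepted and uncategorized
terms are excluded from the release but never deleted from the store.

Two merge operations manage datasets at scale: *merge unfinalized* unions
open datasets of one taxon group into a single deduplicated dataset
(keeping every source sentence and every decision with its original
author and timestamp), and *merge into system* folds finalized results
into the admin-managed system glossary of the group, re-finalizing it
with a new version.
"""
from __future__ import annotations

import copy
import json
from typing import Optional

from . import grouping as grp
from . import hierarchy as hier
from . import ordering as ords
from .errors import (FrozenTermSetError, InvalidOperation, PermissionDenied,
                     UnknownName)
from .model import (SYSTEM_USER, Category, Categorization, GlossaryVersion,
                    SynonymLink, Term, TermSet, TermSetStats, TreeNode,
                    normalize_term)


def conflict_rate_percent(conflict_categorizations: int,
                          categorizations: int) -> float:
    """Percentage of categorizations in conflict, rounded to one decimal.

    Zero when no categorizations exist.
    """
    if categorizations == 0:
        return 0.0
    return round(100.0 * conflict_categorizations / categorizations, 1)


def _order_sig_json(saved_boxes) -> str:
    return json.dumps([sorted(b) for b in saved_boxes])


def _require_reviewer(ws, caller, term_set: TermSet):
    dataset = ws.dataset_of(term_set)
    caller = ws.get_user(caller)
    if not ws.check_permission(caller, "finalize", dataset):
        raise PermissionDenied(
            f"{caller.username!r} may not review/finalize {dataset.name!r}")
    return caller, dataset


# ---------------------------------------------------------------------------
# review and approval
# ---------------------------------------------------------------------------

def review(ws, reviewer, term_set: TermSet) -> list:
    """All distinct decisions in a term set, with their supporter sets and
    acceptance status.  Side-effect free."""
    _require_reviewer(ws, reviewer, term_set)
    accepted = set(term_set.data.accepted)
    decisions: dict[tuple, set] = {}
    if term_set.task == "grouping":
        for r in term_set.data.records:
            if r.current and not r.shadowed:
                decisions.setdefault(("cat", r.term, r.category), set()).add(r.user)
        for l in term_set.data.links:
            if l.active:
                decisions.setdefault(
                    ("syn", l.preferred, l.synonym, l.category), set()).add(l.user)
    elif term_set.task == "hierarchy":
        for p in term_set.data.placements:
            if p.user == SYSTEM_USER:
                continue
            decisions.setdefault(("path", p.term) + tuple(p.path), set()).add(p.user)
    elif term_set.task == "ordering":
        for o in term_set.data.orders:
            sig = o.signature()
            if sig is not None:
                key = ("order", o.group, o.name, _order_sig_json(o.saved_boxes))
                decisions.setdefault(key, set()).add(o.user)
    return [{"key": key, "supporters": sorted(users),
             "accepted": key in accepted}
            for key, users in sorted(decisions.items())]


def _known_keys(ws, reviewer, term_set: TermSet) -> set:
    return {d["key"] for d in review(ws, reviewer, term_set)}


def approve(ws, reviewer, term_set: TermSet, key) -> None:
    """Move one decision into the accepted set.  Several categories may be
    accepted for the same term (the multi-category outcome)."""
    if not term_set.is_open:
        raise FrozenTermSetError("term set is finalized")
    key = tuple(key)
    if key not in _known_keys(ws, reviewer, term_set):
        raise UnknownName(f"no such decision: {key}")
    if key not in term_set.data.accepted:
        term_set.data.accepted.append(key)
    _sync_accepted_flags(term_set)


def reject(ws, reviewer, term_set: TermSet, key) -> None:
    if not term_set.is_open:
        raise FrozenTermSetError("term set is finalized")
    key = tuple(key)
    _require_reviewer(ws, reviewer, term_set)
    if key in term_set.data.accepted:
        term_set.data.accepted.remove(key)
    _sync_accepted_flags(term_set)


def _sync_accepted_flags(term_set: TermSet) -> None:
    accepted = set(term_set.data.accepted)
    if term_set.task == "grouping":
        for r in term_set.data.records:
            r.accepted = ("cat", r.term, r.category) in accepted and r.current
        for l in term_set.data.links:
            l.accepted = (("syn", l.preferred, l.synonym, l.category) in accepted
                          and l.active)
    elif term_set.task == "hierarchy":
        for p in term_set.data.placements:
            p.accepted = ("path", p.term) + tuple(p.path) in accepted
    elif term_set.task == "ordering":
        for o in term_set.data.orders:
            sig = o.signature()
            o.accepted = (sig is not None and
                          ("order", o.group, o.name,
                           _order_sig_json(o.saved_boxes)) in accepted)


def approve_all_system(ws, reviewer, term_set: TermSet, reference) -> int:
    """Accept every pending categorization that matches the reference
    glossary.  Already-accepted matches are not counted again."""
    if term_set.task != "grouping":
        raise InvalidOperation("system approval applies to grouping term sets")
    count = 0
    accepted = set(term_set.data.accepted)
    for d in review(ws, reviewer, term_set):
        key = d["key"]
        if key[0] != "cat" or key in accepted:
            continue
        _, term, category = key
        if category in reference.categories_for(term):
            term_set.data.accepted.append(key)
            accepted.add(key)
            count += 1
    _sync_accepted_flags(term_set)
    return count


# ---------------------------------------------------------------------------
# finalize / reopen
# ---------------------------------------------------------------------------

def participants(term_set: TermSet) -> list:
    users = set()
    if term_set.task == "grouping":
        users |= {r.user for r in term_set.data.records}
        users |= {l.user for l in term_set.data.links}
        users |= {c.user for c in term_set.data.comments}
    elif term_set.task == "hierarchy":
        users |= {p.user for p in term_set.data.placements}
    elif term_set.task == "ordering":
        users |= {o.user for o in term_set.data.orders if o.saved_boxes}
    users.discard(SYSTEM_USER)
    return sorted(users)


def finalize(ws, caller, term_set: TermSet) -> GlossaryVersion:
    """Freeze a term set and release a new glossary version.

    Only accepted decisions enter the release.  Concept UUIDs are
    registered in the workspace-global dictionary, so re-finalizing after
    a reopen (or merging later) reuses the identifiers already minted.
    """
    caller, dataset = _require_reviewer(ws, caller, term_set)
    if not term_set.is_open:
        raise InvalidOperation("term set is already finalized")
    content = _build_content(ws, dataset, term_set)
    if not content["_nonempty"]:
        raise InvalidOperation("nothing accepted; finalize requires at least "
                               "one accepted decision")
    del content["_nonempty"]
    term_set.version = (term_set.version[0], term_set.version[1] + 1)
    term_set.status = "finalized"
    version = GlossaryVersion(
        task=term_set.task, version=term_set.version,
        release_date=ws.clock(), participants=participants(term_set),
        dataset_name=dataset.name, taxon_group=dataset.taxon_group,
        content=content)
    term_set.versions.append(version)
    return version


def _build_content(ws, dataset, term_set: TermSet) -> dict:
    accepted = set(term_set.data.accepted)
    if term_set.task == "grouping":
        syn_keys = [k for k in accepted if k[0] == "syn"]
        cat_keys = [k for k in accepted if k[0] == "cat"]
        # synonym terms never get standalone glossary rows in their category
        synonym_terms = {(k[2], k[3]) for k in syn_keys}
        concepts = []
        for _, term, category in sorted(cat_keys, key=lambda k: (k[2], k[1])):
            if (term, category) in synonym_terms:
                continue
            rec = ws.register_concept(term, category, dataset.taxon_group)
            has_syn = any(k[1] == term and k[3] == category for k in syn_keys)
            t = term_set.terms.get(term)
            concepts.append({
                "term": term, "category": category, "uuid": rec.uuid,
                "has_syn": has_syn,
                "source_datasets": t.documents() if t else [],
            })
        synonyms = []
        for _, pref, syn, category in sorted(syn_keys, key=lambda k: (k[3], k[1], k[2])):
            rec = ws.register_concept(pref, category, dataset.taxon_group)
            synonyms.append({"preferred": pref, "category": category,
                             "uuid": rec.uuid, "synonym": syn})
        used = {c["category"] for c in concepts} | {s["category"] for s in synonyms}
        defs = {name: (term_set.data.categories[name].definition or "")
                for name in sorted(used) if name in term_set.data.categories}
        return {"concepts": concepts, "synonyms": synonyms,
                "category_definitions": defs,
                "_nonempty": bool(concepts or synonyms)}
    if term_set.task == "hierarchy":
        placements = []
        for key in sorted(accepted):
            if key[0] != "path":
                continue
            term, path = key[1], key[2:]
            match = min((p for p in term_set.data.placements
                         if p.term == term and tuple(p.path) == path),
                        key=lambda p: (p.timestamp, p.user), default=None)
            if match is None:
                continue
            placements.append({"term": term, "path": list(path),
                               "userid": match.user,
                               "confirm_date": match.timestamp.isoformat()})
        return {"placements": placements, "_nonempty": bool(placements)}
    if term_set.task == "ordering":
        rows = []
        for key in sorted(accepted):
            if key[0] != "order":
                continue
            _, group, name, sig = key
            match = min((o for o in term_set.data.orders
                         if o.group == group and o.name == name
                         and o.saved_boxes is not None
                         and _order_sig_json(o.saved_boxes) == sig),
                        key=lambda o: (o.timestamp, o.user), default=None)
            if match is None:
                continue
            for row in ords.serialize_order(match):
                rows.append({"order_id": row["order_id"],
                             "order_name": row["order_name"],
                             "term": row["term"], "distance": row["distance"],
                             "userid": row["user"],
                             "confirm_date": row["timestamp"].isoformat()})
        return {"rows": rows, "_nonempty": bool(rows)}
    raise UnknownName(f"unknown task {term_set.task!r}")


def reopen(ws, caller, term_set: TermSet) -> None:
    """Make a finalized term set editable again.  Released versions remain
    immutable and queryable."""
    _require_reviewer(ws, caller, term_set)
    if term_set.is_open:
        raise InvalidOperation("term set is not finalized")
    term_set.status = "open"


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_unfinalized(ws, caller, dataset_names, new_name: str,
                      visibility: Optional[str] = None):
    """Union open datasets of one taxon group into a new dataset.

    Duplicate terms collapse to one (source sentences and documents
    unioned); decisions carry over with their original authors and
    timestamps.  The source datasets are deleted only after the merged
    dataset is durably persisted.
    """
    caller = ws.get_user(caller)
    sources = [ws.get_dataset(n) for n in dataset_names]
    if len(sources) < 2:
        raise InvalidOperation("merging needs at least two datasets")
    if new_name in ws.datasets:
        raise InvalidOperation(f"dataset {new_name!r} already exists")
    groups = {ds.taxon_group for ds in sources}
    if len(groups) != 1:
        raise InvalidOperation(f"datasets span several taxon groups: {sorted(groups)}")
    for ds in sources:
        if not ws.check_permission(caller, "merge", ds):
            raise PermissionDenied(
                f"{caller.username!r} may not merge dataset {ds.name!r}")
        for ts in ds.term_sets.values():
            if not ts.is_open:
                raise InvalidOperation(
                    f"dataset {ds.name!r} has a finalized term set")
    merged = ws.create_dataset(new_name, sources[0].taxon_group, caller,
                               visibility or sources[0].visibility)
    merged.merged_from = [ds.name for ds in sources]
    for ds in sources:
        for doc in ds.source_documents:
            if doc not in merged.source_documents:
                merged.source_documents.append(doc)
    for task in ("grouping", "hierarchy", "ordering"):
        parts = [ds.term_sets[task] for ds in sources if task in ds.term_sets]
        if parts:
            merged.term_sets[task] = _merge_term_sets(task, parts)
    if ws.path is not None:
        ws.save()
    for ds in sources:
        del ws.datasets[ds.name]
    if ws.path is not None:
        ws.save()
    return merged


def _merge_term_sets(task: str, parts) -> TermSet:
    out = TermSet(task=task)
    out.touched = any(p.touched for p in parts)
    for p in parts:
        for key, term in p.terms.items():
            if key in out.terms:
                for doc, sent in term.source_sentences:
                    out.terms[key].add_sentence(doc, sent)
            else:
                out.terms[key] = Term(term.surface, key,
                                      list(term.source_sentences))
    if task == "grouping":
        for p in parts:
            for name, cat in p.data.categories.items():
                out.data.categories.setdefault(name, copy.deepcopy(cat))
            out.data.records.extend(copy.deepcopy(p.data.records))
            out.data.links.extend(copy.deepcopy(p.data.links))
            out.data.comments.extend(copy.deepcopy(p.data.comments))
            for key in p.data.accepted:
                if key not in out.data.accepted:
                    out.data.accepted.append(key)
    elif task == "hierarchy":
        for p in parts:
            if p.data.default_tree is not None:
                out.data.default_tree = p.data.default_tree.copy()
                break
        for p in parts:
            out.data.placements.extend(copy.deepcopy(p.data.placements))
            for user, consumed in p.data.consumed.items():
                dst = out.data.consumed.setdefault(user, [])
                for t in consumed:
                    if t not in dst:
                        dst.append(t)
            for key in p.data.accepted:
                if key not in out.data.accepted:
                    out.data.accepted.append(key)
        _rebuild_trees(out)
    elif task == "ordering":
        for p in parts:
            for name, members in p.data.groups.items():
                dst = out.data.groups.setdefault(name, [])
                for m in members:
                    if m not in dst:
                        dst.append(m)
            for order in p.data.orders:
                clone = copy.deepcopy(order)
                while any(o.user == clone.user and o.group == clone.group
                          and o.name == clone.name for o in out.data.orders):
                    clone.name = clone.name + "~merged"
                    clone.order_id = ords.make_order_id(clone.user, clone.group,
                                                        clone.name)
                out.data.orders.append(clone)
            for key in p.data.accepted:
                if key not in out.data.accepted:
                    out.data.accepted.append(key)
    return out


def _rebuild_trees(term_set: TermSet) -> None:
    """Reconstruct each user's tree from the default tree plus their saved
    placement paths (saved placements fully determine the tree)."""
    data = term_set.data
    if data.default_tree is None:
        return
    data.trees = {}
    by_user: dict[str, list] = {}
    for p in data.placements:
        by_user.setdefault(p.user, []).append(p.path)
    for user, paths in by_user.items():
        tree = data.default_tree.copy()
        for path in sorted(paths, key=len):
            node = tree
            for term in path[1:]:
                child = next((c for c in node.children if c.term == term), None)
                if child is None:
                    child = TreeNode(term=term, saved=True)
                    node.children.append(child)
                node = child
            node.saved = True
        data.trees[user] = tree


def merge_into_system(ws, caller, source_names, system_name) -> GlossaryVersion:
    """Fold finalized grouping results into the system reserved glossary of
    the same taxon group and re-finalize it with a new version.

    Concepts are deduplicated by their ⟨term, category, taxon group⟩
    triple; triples already in the global dictionary keep their UUIDs.
    The source datasets are deleted from the store (their released output
    files are untouched).
    """
    caller = ws.get_user(caller)
    if not caller.is_admin:
        raise PermissionDenied("merging into a system glossary is admin-only")
    system = ws.get_dataset(system_name)
    if system.visibility != "system_reserved":
        raise InvalidOperation(f"{system.name!r} is not system reserved")
    sources = [ws.get_dataset(n) for n in source_names]
    for ds in sources:
        if ds.taxon_group != system.taxon_group:
            raise InvalidOperation(
                f"{ds.name!r} is for {ds.taxon_group!r}, "
                f"not {system.taxon_group!r}")
        ts = ds.term_sets.get("grouping")
        if ts is None or ts.is_open or not ts.versions:
            raise InvalidOperation(f"dataset {ds.name!r} is not finalized")
    sys_ts = system.term_sets.get("grouping")
    if sys_ts is None:
        sys_ts = TermSet(task="grouping")
        system.term_sets["grouping"] = sys_ts
    if not sys_ts.is_open:
        sys_ts.status = "open"   # internal reopen for the automatic re-finalize
    for ds in sources:
        content = ds.term_sets["grouping"].versions[-1].content
        defs = content.get("category_definitions", {})
        for concept in content.get("concepts", []):
            _absorb_concept(ws, sys_ts, concept, defs)
        for syn in content.get("synonyms", []):
            _absorb_synonym(ws, sys_ts, syn)
    version = finalize(ws, caller, sys_ts)
    if ws.path is not None:
        ws.save()
    for ds in sources:
        del ws.datasets[ds.name]
    if ws.path is not None:
        ws.save()
    return version


def _absorb_concept(ws, sys_ts: TermSet, concept: dict, defs: dict) -> None:
    term, category = concept["term"], concept["category"]
    if term not in sys_ts.terms:
        sys_ts.terms[term] = Term(term, term)
    for doc in concept.get("source_datasets", []):
        sys_ts.terms[term].add_sentence(doc, "")
    if category not in sys_ts.data.categories:
        sys_ts.data.categories[category] = Category(
            category, defs.get(category) or None, origin="system_copied")
    key = ("cat", term, category)
    if key not in sys_ts.data.accepted:
        sys_ts.data.records.append(Categorization(
            user=SYSTEM_USER, term=term, category=category,
            timestamp=ws.clock(), accepted=True))
        sys_ts.data.accepted.append(key)


def _absorb_synonym(ws, sys_ts: TermSet, syn: dict) -> None:
    pref, category, synonym = syn["preferred"], syn["category"], syn["synonym"]
    for t in (pref, synonym):
        if t not in sys_ts.terms:
            sys_ts.terms[t] = Term(t, t)
    key = ("syn", pref, synonym, category)
    if key not in sys_ts.data.accepted:
        sys_ts.data.links.append(SynonymLink(
            user=SYSTEM_USER, preferred=pref, synonym=synonym,
            category=category, timestamp=ws.clock(), accepted=True))
        sys_ts.data.accepted.append(key)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def stats(term_set: TermSet) -> TermSetStats:
    """Curation statistics for a grouping term set.

    A categorization record counts as *in conflict* when its term is
    conflicted (users hold non-identical decision signatures for it); the
    conflict rate is the percentage of such records among all
    categorization records ever made.  Concepts are accepted
    ⟨term, category⟩ pairs.
    """
    if term_set.task != "grouping":
        raise InvalidOperation("statistics are defined for grouping term sets")
    data = term_set.data
    users = ({r.user for r in data.records} | {l.user for l in data.links}
             | {c.user for c in data.comments})
    users.discard(SYSTEM_USER)
    categorizations = len(data.records)
    conflicted = grp.detect_conflicts(term_set)
    conflict_cats = sum(1 for r in data.records if r.term in conflicted)
    accepted_cats = [k for k in data.accepted if k[0] == "cat"]
    per_term: dict[str, int] = {}
    for _, term, _cat in accepted_cats:
        per_term[term] = per_term.get(term, 0) + 1
    return TermSetStats(
        unique_terms=len(term_set.terms),
        users=len(users),
        categorizations=categorizations,
        conflict_categorizations=conflict_cats,
        comments=len(data.comments),
        concepts=len(accepted_cats),
        multi_category_terms=sum(1 for n in per_term.values() if n >= 2),
        conflict_rate=conflict_rate_percent(conflict_cats, categorizations),
    )
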