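"""The Group Terms workflow: is_a categorization and synonymy.

Users place terms into categories, copy a term into additional categories
when it is a homonym (``sweet`` as a taste and as a smell are two distinct
concepts), and link synonyms onto a preferred term within a category.
Every decision is timestamped and kept forever; a user's *current* decision
set is what the working view, conflict detection, and finalization see.

Conflict semantics: a term is conflicted when at least two users hold
non-identical decision signatures for it, where a user's signature is the
pair (set of current categories, set of active synonym links touching the
term).  Synonym links are part of the signature because synonymizing is a
categorization decision — reviewers adjudicate both at finalization.
"""
from __future__ import annotations

from typing import Optional

from .errors import (CycleError, DuplicateName, FrozenTermSetError,
                     InvalidOperation, UnknownName)
from .model import (SYSTEM_USER, Categorization, Category, Comment,
                    ReferenceGlossary, SynonymLink, TermSet, normalize_term)


def _username(user) -> str:
    return user if isinstance(user, str) else user.username


def _require_open(term_set: TermSet) -> None:
    if not term_set.is_open:
        raise FrozenTermSetError("term set is finalized; decisions are frozen")


def _require_term(term_set: TermSet, term: str) -> str:
    key = normalize_term(term)
    if key not in term_set.terms:
        raise UnknownName(f"term {term!r} is not in this term set")
    return key


# ---------------------------------------------------------------------------
# categories and assignment
# ---------------------------------------------------------------------------

def create_category(ws, term_set: TermSet, user, name: str,
                    definition: Optional[str] = None,
                    origin: str = "user_created") -> Category:
    _require_open(term_set)
    if not name:
        raise InvalidOperation("category name must be non-empty")
    if name in term_set.data.categories:
        raise DuplicateName(f"category {name!r} already exists")
    cat = Category(name, definition, origin)
    term_set.data.categories[name] = cat
    term_set.touched = True
    return cat


def current_records(term_set: TermSet, user: str, term: Optional[str] = None):
    """The user's live (non-superseded) categorizations, optionally for one term."""
    return [r for r in term_set.data.records
            if r.user == user and r.current
            and (term is None or r.term == term)]


def active_links(term_set: TermSet, user: Optional[str] = None):
    return [l for l in term_set.data.links
            if l.active and (user is None or l.user == user)]


def assign(ws, term_set: TermSet, user, terms, category: str) -> list:
    """Assign one or more terms to a category, replacing each term's
    previous current decision for this user (history is kept)."""
    _require_open(term_set)
    username = _username(user)
    if category not in term_set.data.categories:
        raise UnknownName(f"unknown category {category!r}")
    if isinstance(terms, str):
        terms = [terms]
    keys = [_require_term(term_set, t) for t in terms]
    out = []
    for key in keys:
        for rec in current_records(term_set, username, key):
            rec.current = False
        rec = Categorization(user=username, term=key, category=category,
                             timestamp=ws.clock())
        term_set.data.records.append(rec)
        out.append(rec)
    term_set.touched = True
    return out


def copy_assign(ws, term_set: TermSet, user, term: str, category: str):
    """Copy a term into an additional category (homonym case).

    Requires a prior saved decision for the term; afterwards the term's
    display aliases are ``base_1 .. base_k`` in assignment order.
    """
    _require_open(term_set)
    username = _username(user)
    key = _require_term(term_set, term)
    if category not in term_set.data.categories:
        raise UnknownName(f"unknown category {category!r}")
    existing = current_records(term_set, username, key)
    if not existing:
        raise InvalidOperation(
            "copy requires a previously saved categorization for the term")
    if any(r.category == category for r in existing):
        raise DuplicateName(
            f"{term!r} is already in category {category!r} for this user")
    rec = Categorization(user=username, term=key, category=category,
                         timestamp=ws.clock())
    term_set.data.records.append(rec)
    term_set.touched = True
    return rec, homonym_aliases(term_set, username, key)


def homonym_aliases(term_set: TermSet, user, term: str) -> list:
    """Display aliases for a multi-category term: ``base_i`` with i = 1..k
    in assignment order.  Aliases are presentation-only; every export
    carries the bare base term."""
    username = _username(user)
    key = normalize_term(term)
    recs = sorted(current_records(term_set, username, key),
                  key=lambda r: (r.timestamp, r.category))
    if len(recs) < 2:
        return []
    return [f"{key}_{i}" for i in range(1, len(recs) + 1)]


# ---------------------------------------------------------------------------
# synonyms
# ---------------------------------------------------------------------------

def synonymize(ws, term_set: TermSet, user, synonym_term: str,
               preferred_term: str, category: Optional[str] = None) -> SynonymLink:
    """Link ``synonym_term`` onto ``preferred_term`` within a shared category.

    Both terms must already carry a saved categorization by this user, and
    the link is made in a category they share (inferred when unambiguous).
    The accepted relation per category is a star forest: a synonym has
    exactly one preferred term and is never itself preferred.
    """
    _require_open(term_set)
    username = _username(user)
    syn = _require_term(term_set, synonym_term)
    pref = _require_term(term_set, preferred_term)
    if syn == pref:
        raise CycleError("a term cannot be its own synonym")
    syn_cats = {r.category for r in current_records(term_set, username, syn)}
    pref_cats = {r.category for r in current_records(term_set, username, pref)}
    if not syn_cats or not pref_cats:
        raise InvalidOperation(
            "both terms must have saved categorization decisions first")
    shared = syn_cats & pref_cats
    if category is None:
        if len(shared) != 1:
            raise InvalidOperation(
                f"shared category is ambiguous or empty: {sorted(shared)}")
        category = next(iter(shared))
    elif category not in shared:
        raise InvalidOperation(
            f"terms do not share category {category!r} for this user")
    for link in active_links(term_set, username):
        if link.category != category:
            continue
        if link.synonym == syn:
            raise InvalidOperation(
                f"{synonym_term!r} already has a preferred term in {category!r}")
        if link.preferred == syn:
            raise CycleError(
                f"{synonym_term!r} is a preferred term in {category!r}; "
                "linking it as a synonym would create a cycle")
        if link.synonym == pref:
            raise CycleError(
                f"{preferred_term!r} is already a synonym in {category!r}")
    link = SynonymLink(user=username, preferred=pref, synonym=syn,
                       category=category, timestamp=ws.clock())
    term_set.data.links.append(link)
    # the synonym's standalone decision in this category stops emitting its
    # own glossary row, but is retained so unsynonymize can revert it
    for rec in current_records(term_set, username, syn):
        if rec.category == category:
            rec.shadowed = True
    term_set.touched = True
    return link


def unsynonymize(ws, term_set: TermSet, user, link: SynonymLink) -> None:
    """Dissolve a synonym link; the synonym reverts to a standalone
    categorization for this user.  The link stays in the history."""
    _require_open(term_set)
    username = _username(user)
    if link not in term_set.data.links or not link.active or link.user != username:
        raise UnknownName("no such active synonym link for this user")
    link.active = False
    for rec in current_records(term_set, username, link.synonym):
        if rec.category == link.category:
            rec.shadowed = False
    term_set.touched = True


def find_link(term_set: TermSet, user, synonym_term: str,
              preferred_term: str) -> SynonymLink:
    username = _username(user)
    syn = normalize_term(synonym_term)
    pref = normalize_term(preferred_term)
    for link in active_links(term_set, username):
        if link.synonym == syn and link.preferred == pref:
            return link
    raise UnknownName(
        f"no active link {synonym_term!r} -> {preferred_term!r} for {username!r}")


# ---------------------------------------------------------------------------
# reference decisions
# ---------------------------------------------------------------------------

def copy_system_decisions(ws, term_set: TermSet,
                          reference: ReferenceGlossary,
                          taxon_group: Optional[str] = None) -> int:
    """Pre-seed categorizations from a reference glossary of the same taxon
    group, recorded under the reserved ``system`` user.  Users may later
    override with their own decisions; the system record stays in history.
    Returns the number of terms matched."""
    _require_open(term_set)
    if taxon_group is not None and reference.taxon_group != taxon_group:
        raise InvalidOperation(
            f"reference glossary is for {reference.taxon_group!r}, "
            f"not {taxon_group!r}")
    matched = 0
    for key in term_set.terms:
        entries = reference.entries.get(key)
        if not entries:
            continue
        if current_records(term_set, SYSTEM_USER, key):
            continue
        for category, definition in entries:
            if category not in term_set.data.categories:
                term_set.data.categories[category] = Category(
                    category, definition, origin="system_copied")
            term_set.data.records.append(Categorization(
                user=SYSTEM_USER, term=key, category=category,
                timestamp=ws.clock()))
        matched += 1
    if matched:
        term_set.touched = True
    return matched


# ---------------------------------------------------------------------------
# views, conflicts, reports
# ---------------------------------------------------------------------------

def user_signature(term_set: TermSet, user: str, term: str):
    """A user's decision signature for a term: (category set, link set).

    Returns ``None`` when the user holds no decision touching the term.
    Categories shadowed by a synonym link are carried by the link itself.
    """
    key = normalize_term(term)
    cats = frozenset(r.category for r in current_records(term_set, user, key)
                     if not r.shadowed)
    links = frozenset(l.key for l in active_links(term_set, user)
                      if key in (l.preferred, l.synonym))
    if not cats and not links:
        return None
    return (cats, links)


def _deciders(term_set: TermSet, term: str) -> list:
    users = set()
    for r in term_set.data.records:
        if r.current and r.term == term:
            users.add(r.user)
    for l in term_set.data.links:
        if l.active and term in (l.preferred, l.synonym):
            users.add(l.user)
    return sorted(users)


def working_view(term_set: TermSet) -> dict:
    """Most-recent decision view across all users.

    Each term maps to ``(categories, links, decided_by)`` taken from the
    user whose latest current decision for the term is newest; timestamp
    ties break by username so the view is deterministic.  Terms nobody has
    categorized map to an empty category set.
    """
    out = {}
    for key in term_set.terms:
        best = None
        for user in _deciders(term_set, key):
            stamps = [r.timestamp for r in current_records(term_set, user, key)]
            stamps += [l.timestamp for l in active_links(term_set, user)
                       if key in (l.preferred, l.synonym)]
            latest = max(stamps)
            if best is None or (latest, user) > (best[0], best[1]):
                best = (latest, user)
        if best is None:
            out[key] = (frozenset(), frozenset(), None)
        else:
            sig = user_signature(term_set, best[1], key)
            out[key] = (sig[0], sig[1], best[1])
    return out


def detect_conflicts(term_set: TermSet) -> set:
    """Terms on which at least two users hold non-identical signatures."""
    conflicted = set()
    for key in term_set.terms:
        sigs = {}
        for user in _deciders(term_set, key):
            sig = user_signature(term_set, user, key)
            if sig is not None:
                sigs[user] = sig
        if len(sigs) >= 2 and len(set(sigs.values())) > 1:
            conflicted.add(key)
    return conflicted


def comment(ws, term_set: TermSet, user, term: str, text: str) -> Comment:
    key = _require_term(term_set, term)
    c = Comment(user=_username(user), term=key, text=text, timestamp=ws.clock())
    term_set.data.comments.append(c)
    return c


def locations(term_set: TermSet, term: str) -> list:
    """Current categories a term resides in, per the working view.  Any
    term may be searched; unknown terms yield an empty list."""
    key = normalize_term(term)
    if key not in term_set.terms:
        return []
    cats, links, _ = working_view(term_set)[key]
    extra = {l[2] for l in links if l[1] == key}   # synonym placed via link
    return sorted(cats | extra)


def context(term_set: TermSet, term: str) -> list:
    """All imported (document, sentence) pairs for a term; empty when the
    term is unknown or was imported without sentences."""
    t = term_set.get_term(term)
    return list(t.source_sentences) if t else []


def report(term_set: TermSet, term: str) -> dict:
    """Complete per-term report: chronological decision history (including
    superseded and system decisions), comments, and the conflict flag."""
    key = _require_term(term_set, term)
    events = [r for r in term_set.data.records if r.term == key]
    events += [l for l in term_set.data.links
               if key in (l.preferred, l.synonym)]
    events.sort(key=lambda e: (e.timestamp, e.user))
    return {
        "term": key,
        "history": events,
        "comments": [c for c in term_set.data.comments if c.term == key],
        "conflicted": key in detect_conflicts(term_set),
    }
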