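import random

import pytest

from termorg import Workspace, grouping
from termorg.clock import TickClock


@pytest.fixture
def ws():
    """Fresh in-memory workspace with a deterministic clock."""
    w = Workspace(clock=TickClock())
    w.add_user("alice")
    w.add_user("bob")
    w.add_user("carol")
    w.add_user("root", role="admin")
    return w


@pytest.fixture
def demo(ws):
    """A small public Plant dataset with a grouping term set."""
    ds = ws.create_dataset("Demo", "Plant", "alice", "public")
    ts = ws.import_term_set(
        ds, "grouping", ["leaf", "alternate", "stipule", "petiole"],
        default_categories=[("structure", "A plant organ or part."),
                            ("arrangement", "How organs are positioned.")])
    return ds, ts


def random_grouping_session(ws, n_users, n_terms, seed, n_categories=4,
                            copy_prob=0.15, skip_prob=0.2):
    """Scripted random categorization activity used by conflict-oracle tests."""
    rng = random.Random(seed)
    users = [f"user{i}" for i in range(n_users)]
    terms = [f"t{i}" for i in range(n_terms)]
    cats = [f"c{i}" for i in range(n_categories)]
    name = f"rand{seed}"
    if "owner" not in ws.users:
        ws.add_user("owner")
    ds = ws.create_dataset(name, "Plant", "owner", "public")
    ts = ws.import_term_set(ds, "grouping", terms, default_categories=cats)
    for term in terms:
        for user in users:
            if rng.random() < skip_prob:
                continue
            grouping.assign(ws, ts, user, [term], rng.choice(cats))
            if rng.random() < copy_prob:
                others = [c for c in cats
                          if c not in {r.category for r in
                                       grouping.current_records(ts, user, term)}]
                if others:
                    grouping.copy_assign(ws, ts, user, term, rng.choice(others))
    return ds, ts


# ---------------------------------------------------------------------------
# independent brute-force conflict oracles
# ---------------------------------------------------------------------------

def oracle_grouping_conflicts(term_set):
    """Exhaustive pairwise signature comparison straight off the raw
    decision records, independent of the library's grouping module."""
    users = {r.user for r in term_set.data.records if r.current}
    users |= {l.user for l in term_set.data.links if l.active}
    conflicted = set()
    for term in term_set.terms:
        sigs = []
        for user in users:
            cats = frozenset(r.category for r in term_set.data.records
                             if r.user == user and r.current
                             and not r.shadowed and r.term == term)
            links = frozenset(
                (l.preferred, l.synonym, l.category)
                for l in term_set.data.links
                if l.user == user and l.active
                and term in (l.preferred, l.synonym))
            if cats or links:
                sigs.append((cats, links))
        if any(a != b for i, a in enumerate(sigs) for b in sigs[i + 1:]):
            conflicted.add(term)
    return conflicted


def oracle_hierarchy_conflicts(term_set):
    per_term = {}
    for p in term_set.data.placements:
        per_term.setdefault(p.term, {}).setdefault(p.user, set()).add(tuple(p.path))
    conflicted = set()
    for term, by_user in per_term.items():
        sets = list(by_user.values())
        if any(a != b for i, a in enumerate(sets) for b in sets[i + 1:]):
            conflicted.add(term)
    return conflicted


def oracle_ordering_conflicts(term_set):
    per_name = {}
    for o in term_set.data.orders:
        if o.saved_boxes is not None:
            sig = tuple(frozenset(b) for b in o.saved_boxes)
            per_name.setdefault((o.group, o.name), {})[o.user] = sig
    conflicted = set()
    for (group, name), by_user in per_name.items():
        sigs = list(by_user.values())
        if any(a != b for i, a in enumerate(sigs) for b in sigs[i + 1:]):
            conflicted.add(name)
    return conflicted
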