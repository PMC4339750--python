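"""Deterministic synthetic curation sessions.

The generator emulates what a multi-user curation campaign produces: a
term list extracted from source sentences, a category inventory, and a
scripted sequence of per-user decisions.  The first user assigns every
term a base category; each further user independently deviates to another
category with probability ``disagreement_prob``, so for ``k`` users a
term ends up conflicted with probability ``1 - (1 - p)^(k-1)``.  Synonym
and homonym (multi-category copy) events are injected at their own rates,
always by the first user, mirroring how a lead curator links variant
terms onto preferred ones.

Identical spec + seed yields a byte-identical bundle and decision script.
The generated data is synthetic: terms are opaque tokens (``t0001``), so
no linguistic structure — and none of the judgment noise of real experts
— is present.
"""
from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from . import grouping
from .errors import InvalidOperation
from .glossary_io import ImportBundle, write_import_bundle
from .model import Term, normalize_term


@dataclass
class FixtureSpec:
    """Parameters of a synthetic curation session.

    Defaults describe a small, realistically contentious session: a few
    curators, a disagreement rate in the range observed in real multi-user
    campaigns, and occasional synonym/homonym decisions.
    """

    n_terms: int = 200
    n_users: int = 3
    n_categories: int = 8
    disagreement_prob: float = 0.3
    synonym_prob: float = 0.05
    homonym_prob: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("disagreement_prob", "synonym_prob", "homonym_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidOperation(f"{name} must be in [0, 1], got {p}")
        if self.n_terms < 1 or self.n_users < 1 or self.n_categories < 2:
            raise InvalidOperation("need >=1 term, >=1 user, >=2 categories")


def expected_conflict_fraction(spec: FixtureSpec) -> float:
    """Closed-form expected conflicted-term fraction for >=2 users (ignores
    synonym/homonym events): 1 - (1 - p)^(k-1)."""
    return 1.0 - (1.0 - spec.disagreement_prob) ** (spec.n_users - 1)


def _usernames(spec: FixtureSpec) -> list:
    return [f"u{i:02d}" for i in range(1, spec.n_users + 1)]


def generate_script(spec: FixtureSpec):
    """Produce (bundle, decision script) without touching the filesystem."""
    spec.validate()
    rng = random.Random(spec.seed)
    categories = [f"c{i:02d}" for i in range(1, spec.n_categories + 1)]
    terms = [f"t{i:04d}" for i in range(1, spec.n_terms + 1)]
    users = _usernames(spec)
    docs = [f"vol{i}" for i in range(1, 4)]

    bundle = ImportBundle(
        name=f"fixture_{spec.seed}", taxon_group="Plant",
        visibility="public", owner=users[0],
        default_categories=[(c, f"Synthetic category {c}.") for c in categories])
    for i, t in enumerate(terms):
        doc = docs[i % len(docs)]
        bundle.grouping_terms.append(Term(t, normalize_term(t)))
        bundle.sentences.append(
            (t, doc, f"The specimen margin is {t} toward the apex."))

    script = []
    preferred_pool: dict[str, str] = {}   # base category -> preferred term
    for t in terms:
        base = rng.choice(categories)
        script.append({"op": "assign", "user": users[0], "term": t,
                       "category": base})
        for user in users[1:]:
            if rng.random() < spec.disagreement_prob:
                other = rng.choice([c for c in categories if c != base])
                script.append({"op": "assign", "user": user, "term": t,
                               "category": other})
            else:
                script.append({"op": "assign", "user": user, "term": t,
                               "category": base})
        if rng.random() < spec.homonym_prob:
            extra = rng.choice([c for c in categories if c != base])
            script.append({"op": "copy", "user": users[0], "term": t,
                           "category": extra})
        if rng.random() < spec.synonym_prob and base in preferred_pool:
            script.append({"op": "synonymize", "user": users[0],
                           "synonym": t, "preferred": preferred_pool[base],
                           "category": base})
        else:
            preferred_pool.setdefault(base, t)
    return bundle, script


def generate_fixture(spec: FixtureSpec, directory):
    """Write the bundle directory plus ``decisions.json``; returns
    (bundle path, script)."""
    bundle, script = generate_script(spec)
    directory = Path(directory)
    write_import_bundle(bundle, directory)
    (directory / "decisions.json").write_text(
        json.dumps(script, indent=0) + "\n", encoding="utf-8")
    return directory, script


def replay_script(ws, term_set, script) -> None:
    """Apply a decision script to a grouping term set."""
    for op in script:
        kind = op["op"]
        if kind == "assign":
            grouping.assign(ws, term_set, op["user"], [op["term"]],
                            op["category"])
        elif kind == "copy":
            grouping.copy_assign(ws, term_set, op["user"], op["term"],
                                 op["category"])
        elif kind == "synonymize":
            grouping.synonymize(ws, term_set, op["user"], op["synonym"],
                                op["preferred"], op.get("category"))
        elif kind == "unsynonymize":
            link = grouping.find_link(term_set, op["user"], op["synonym"],
                                      op["preferred"])
            grouping.unsynonymize(ws, term_set, op["user"], link)
        elif kind == "comment":
            grouping.comment(ws, term_set, op["user"], op["term"], op["text"])
        else:
            raise InvalidOperation(f"unknown scripted op {kind!r}")


def build_session(spec: FixtureSpec, ws=None):
    """Generate, import, and replay a synthetic session in one step.

    Returns ``(workspace, dataset, grouping term set, script)``.
    """
    from .glossary_io import load_bundle
    from .store import Workspace
    from .clock import TickClock

    if ws is None:
        ws = Workspace(clock=TickClock())
    bundle, script = generate_script(spec)
    ds = load_bundle(ws, bundle)
    for user in _usernames(spec):
        if user not in ws.users:
            ws.add_user(user)
    ts = ds.term_sets["grouping"]
    replay_script(ws, ts, script)
    return ws, ds, ts, script
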