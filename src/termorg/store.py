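"""Workspace: users, datasets, the concept dictionary, and persistence.

The workspace persists as a single JSON document (``workspace.json`` inside
a workspace directory), so a curation session survives process restarts and
the store stays inspectable with any text tool.  Saving is atomic: the file
is written to a temporary sibling and renamed into place.

The concept dictionary is workspace-global and append-only.  It lives at
the workspace level — not inside any dataset — so deleting a dataset can
never orphan a concept identifier.
"""
from __future__ import annotations

import json
import os
import re
import uuid as uuidlib
from pathlib import Path
from typing import Optional

from .clock import SystemClock, clock_from_dict
from .errors import (DuplicateName, InvalidOperation, PermissionDenied,
                     UnknownName)
from .model import (SYSTEM_USER, TASKS, VISIBILITIES, ConceptRecord, Dataset,
                    ReferenceGlossary, Term, TermSet, User, normalize_term)

ACTIONS = ("organize", "manage", "finalize", "merge", "delete", "manage_system")

_SYSTEM_NAME_RE = re.compile(r"^([A-Z][A-Za-z0-9]*)_glossary$")

STORE_FILENAME = "workspace.json"


class Workspace:
    """In-memory curation store with optional on-disk persistence."""

    def __init__(self, path: Optional[os.PathLike] = None, clock=None):
        self.path = Path(path) if path is not None else None
        self.clock = clock or SystemClock()
        self.users: dict[str, User] = {}
        self.datasets: dict[str, Dataset] = {}
        #: (term, category, taxon_group) -> ConceptRecord
        self.concepts: dict[tuple, ConceptRecord] = {}
        self.references: dict[str, ReferenceGlossary] = {}

    # -- users -------------------------------------------------------------

    def add_user(self, username: str, role: str = "regular",
                 external_ontology_id: Optional[str] = None) -> User:
        if username == SYSTEM_USER:
            raise InvalidOperation(
                f"username {SYSTEM_USER!r} is reserved for copied reference decisions")
        if username in self.users:
            raise DuplicateName(f"user {username!r} already exists")
        user = User(username, role, external_ontology_id)
        self.users[username] = user
        return user

    def get_user(self, username) -> User:
        if isinstance(username, User):
            return username
        try:
            return self.users[username]
        except KeyError:
            raise UnknownName(f"unknown user {username!r}") from None

    # -- datasets ----------------------------------------------------------

    def create_dataset(self, name: str, taxon_group: str, owner,
                       visibility: str = "public") -> Dataset:
        owner = self.get_user(owner)
        if name in self.datasets:
            raise DuplicateName(f"dataset {name!r} already exists")
        if visibility not in VISIBILITIES:
            raise InvalidOperation(f"unknown visibility {visibility!r}")
        if visibility == "system_reserved":
            if not owner.is_admin:
                raise PermissionDenied(
                    "only an administrator may create a system reserved dataset")
            m = _SYSTEM_NAME_RE.match(name)
            if not m or m.group(1) != taxon_group:
                raise InvalidOperation(
                    f"system reserved dataset name must be {taxon_group}_glossary")
        ds = Dataset(name=name, taxon_group=taxon_group, owner=owner.username,
                     visibility=visibility)
        self.datasets[name] = ds
        return ds

    def get_dataset(self, name) -> Dataset:
        if isinstance(name, Dataset):
            return name
        try:
            return self.datasets[name]
        except KeyError:
            raise UnknownName(f"unknown dataset {name!r}") from None

    def dataset_of(self, term_set: TermSet) -> Dataset:
        for ds in self.datasets.values():
            if term_set in ds.term_sets.values():
                return ds
        raise UnknownName("term set does not belong to any dataset in this workspace")

    def delete_dataset(self, caller, dataset) -> None:
        """Remove a dataset with all its term sets and decisions.

        Concept records are untouched: the dictionary is global and
        permanent, so identifiers minted from this dataset stay resolvable.
        """
        caller = self.get_user(caller)
        dataset = self.get_dataset(dataset)
        if not self.check_permission(caller, "delete", dataset):
            raise PermissionDenied(
                f"{caller.username!r} may not delete dataset {dataset.name!r}")
        del self.datasets[dataset.name]

    # -- term-set import ---------------------------------------------------

    def import_term_set(self, dataset, task: str, terms, caller=None,
                        default_categories=None, default_paths=None,
                        term_groups=None) -> TermSet:
        """Create or replace the dataset's term set for one task.

        ``terms`` may be strings or :class:`~termorg.model.Term` objects.
        Duplicate normalized forms collapse into one term whose source
        sentences are unioned.  Re-import is only allowed while the
        existing term set is untouched (no decision ever recorded).
        """
        dataset = self.get_dataset(dataset)
        if caller is not None:
            caller = self.get_user(caller)
            if not (caller.is_admin or caller.username == dataset.owner):
                raise PermissionDenied(
                    f"{caller.username!r} may not import into {dataset.name!r}")
        if task not in TASKS:
            raise UnknownName(f"unknown task {task!r}")
        existing = dataset.term_sets.get(task)
        if existing is not None and existing.touched:
            raise InvalidOperation(
                f"the {task} term set of {dataset.name!r} has been organized "
                "and cannot be re-imported")
        materialized = self._collapse_terms(terms)
        if not materialized:
            raise InvalidOperation("cannot import an empty term list")
        ts = TermSet(task=task, terms=materialized)
        if task == "grouping" and default_categories:
            from .model import Category
            for entry in default_categories:
                if isinstance(entry, str):
                    name, definition = entry, None
                else:
                    name, definition = entry
                ts.data.categories[name] = Category(name, definition,
                                                    origin="imported_default")
        if task == "ordering" and term_groups:
            for group, members in term_groups.items():
                ts.data.groups[group] = [normalize_term(m) for m in members]
        dataset.term_sets[task] = ts
        for term in materialized.values():
            for doc in term.documents():
                if doc not in dataset.source_documents:
                    dataset.source_documents.append(doc)
        if task == "hierarchy":
            from . import hierarchy
            hierarchy.init_hierarchy(ts, default_paths or [],
                                     taxon_group=dataset.taxon_group)
        return ts

    @staticmethod
    def _collapse_terms(terms) -> dict:
        out: dict[str, Term] = {}
        for t in terms:
            if isinstance(t, str):
                t = Term(surface=t, normalized=normalize_term(t))
            key = t.normalized or normalize_term(t.surface)
            if key in out:
                for doc, sent in t.source_sentences:
                    out[key].add_sentence(doc, sent)
            else:
                out[key] = Term(t.surface, key, list(t.source_sentences))
        return out

    # -- concept dictionary ------------------------------------------------

    def register_concept(self, term: str, category: str,
                         taxon_group: str) -> ConceptRecord:
        """Return the permanent record for a concept triple, minting a fresh
        version-4 UUID on first registration (idempotent afterwards)."""
        if not term or not category or not taxon_group:
            raise InvalidOperation("concept triple components must be non-empty")
        triple = (normalize_term(term), category, taxon_group)
        rec = self.concepts.get(triple)
        if rec is None:
            rec = ConceptRecord(*triple, uuid=str(uuidlib.uuid4()))
            self.concepts[triple] = rec
        return rec

    # -- reference glossaries ----------------------------------------------

    def add_reference_glossary(self, caller, name: str, taxon_group: str,
                               entries: dict) -> ReferenceGlossary:
        caller = self.get_user(caller)
        if not caller.is_admin:
            raise PermissionDenied("reference glossaries are admin-managed")
        norm = {}
        for term, ents in entries.items():
            norm[normalize_term(term)] = [
                (e, None) if isinstance(e, str) else tuple(e) for e in ents]
        ref = ReferenceGlossary(name, taxon_group, norm)
        self.references[name] = ref
        return ref

    def reference_for(self, taxon_group: str) -> Optional[ReferenceGlossary]:
        for ref in self.references.values():
            if ref.taxon_group == taxon_group:
                return ref
        return None

    # -- permissions -------------------------------------------------------

    def check_permission(self, user, action: str, dataset) -> bool:
        """Role/visibility permission matrix.

        Any approved user may organize public and system reserved term
        sets; private sets are organized by their owner only.  Owners
        additionally manage, finalize, merge, and delete their own
        datasets — except system reserved ones, which only administrators
        manage.  Administrators may do everything.
        """
        if action not in ACTIONS:
            raise UnknownName(f"unknown action {action!r}")
        user = self.get_user(user)
        dataset = self.get_dataset(dataset)
        if user.is_admin:
            return True
        is_owner = dataset.owner == user.username
        if action == "organize":
            return dataset.visibility in ("public", "system_reserved") or is_owner
        if action == "manage_system":
            return False
        # manage / finalize / merge / delete
        return is_owner and dataset.visibility != "system_reserved"

    # -- glossary query services --------------------------------------------

    def glossary_query(self, kind: str, taxon_group: Optional[str] = None,
                       term: Optional[str] = None):
        """The four read-only query services.

        ``types``
            taxon groups for which at least one finalized grouping glossary
            exists.
        ``latest``
            the highest-version finalized grouping glossary for a group.
        ``categories``
            category names with definitions from that latest glossary.
        ``term_info``
            every (category, definition, taxon group) under which the term
            was finalized, across all groups.
        """
        if kind == "types":
            groups = {ds.taxon_group for ds in self.datasets.values()
                      if self._grouping_versions(ds)}
            return sorted(groups)
        if kind == "latest":
            return self._latest_glossary(taxon_group)
        if kind == "categories":
            latest = self._latest_glossary(taxon_group)
            return dict(latest.content.get("category_definitions", {}))
        if kind == "term_info":
            if not term:
                raise InvalidOperation("term_info requires a non-empty term")
            key = normalize_term(term)
            out = []
            for group in self.glossary_query("types"):
                latest = self._latest_glossary(group)
                defs = latest.content.get("category_definitions", {})
                for concept in latest.content.get("concepts", []):
                    if concept["term"] == key:
                        out.append((concept["category"],
                                    defs.get(concept["category"]), group))
            return out
        raise UnknownName(f"unknown query kind {kind!r}")

    @staticmethod
    def _grouping_versions(ds: Dataset):
        ts = ds.term_sets.get("grouping")
        return ts.versions if ts is not None else []

    def _latest_glossary(self, taxon_group: str):
        if not any(ds.taxon_group == taxon_group for ds in self.datasets.values()):
            raise UnknownName(f"unknown taxon group {taxon_group!r}")
        candidates = []
        for ds in self.datasets.values():
            if ds.taxon_group != taxon_group:
                continue
            # a system reserved glossary outranks peer versions from
            # ordinary datasets of the same group
            rank = 1 if ds.visibility == "system_reserved" else 0
            for v in self._grouping_versions(ds):
                candidates.append((rank, v.version, v))
        if not candidates:
            raise InvalidOperation(
                f"no finalized glossary for taxon group {taxon_group!r} yet")
        return max(candidates, key=lambda c: (c[0], c[1]))[2]

    # -- persistence ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "clock": self.clock.to_dict(),
            "users": [u.to_dict() for u in self.users.values()],
            "datasets": {n: d.to_dict() for n, d in self.datasets.items()},
            "concepts": [c.to_dict() for c in self.concepts.values()],
            "references": {n: r.to_dict() for n, r in self.references.items()},
        }

    @classmethod
    def from_dict(cls, d: dict, path=None) -> "Workspace":
        ws = cls(path=path, clock=clock_from_dict(d.get("clock")))
        for u in d.get("users", []):
            user = User.from_dict(u)
            ws.users[user.username] = user
        for name, dd in d.get("datasets", {}).items():
            ws.datasets[name] = Dataset.from_dict(dd)
        for c in d.get("concepts", []):
            rec = ConceptRecord.from_dict(c)
            ws.concepts[rec.triple] = rec
        for name, r in d.get("references", {}).items():
            ws.references[name] = ReferenceGlossary.from_dict(r)
        return ws

    def save(self, path: Optional[os.PathLike] = None) -> Path:
        """Atomically persist the workspace to ``<dir>/workspace.json``."""
        base = Path(path) if path is not None else self.path
        if base is None:
            raise InvalidOperation("workspace has no persistence path")
        base.mkdir(parents=True, exist_ok=True)
        target = base / STORE_FILENAME
        tmp = target.with_suffix(".json.tmp")
        tmp.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True),
                       encoding="utf-8")
        os.replace(tmp, target)
        self.path = base
        return target

    @classmethod
    def load(cls, path: os.PathLike) -> "Workspace":
        base = Path(path)
        target = base / STORE_FILENAME
        if not target.exists():
            raise UnknownName(f"no workspace at {base}")
        data = json.loads(target.read_text(encoding="utf-8"))
        return cls.from_dict(data, path=base)

    @classmethod
    def open_or_create(cls, path: os.PathLike, clock=None) -> "Workspace":
        base = Path(path)
        if (base / STORE_FILENAME).exists():
            return cls.load(base)
        ws = cls(path=base, clock=clock)
        ws.save()
        return ws
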