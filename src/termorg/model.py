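"""Domain types for collaborative term curation.

A *workspace* holds users, datasets, reference glossaries, and a global,
append-only concept dictionary.  A *dataset* is scoped to a taxon group
(Plant, Hymenoptera, Algae, Porifera, Fossil, ...) and holds up to one
*term set* per organization task:

``grouping``
    is_a categorization of terms into categories, plus synonym links and
    multi-category (homonym) assignment.
``hierarchy``
    part_of placement of structure terms into a rooted tree.
``ordering``
    arrangement of categorical descriptor terms into named orders with
    tie boxes.

Every decision (categorization, synonym link, tree placement, order
snapshot) is recorded per user with a timestamp and never deleted:
superseded decisions stay in the history so term reports can reconstruct
the complete decision trail, while *current* decisions feed the working
view and cross-user conflict detection.

A *concept* is a ⟨term, category, taxon group⟩ triple.  The first time a
triple is finalized it is bound to a random version-4 UUID; the binding is
permanent — reopening, re-finalizing, deleting datasets, and merging never
change it.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

TASKS = ("grouping", "hierarchy", "ordering")
VISIBILITIES = ("private", "public", "system_reserved")
ROLES = ("regular", "admin")

#: Reserved actor used for copied reference decisions and default trees.
SYSTEM_USER = "system"


def normalize_term(surface: str) -> str:
    """Identity key of a term: lower-cased, surrounding whitespace stripped.

    Internal hyphens and spaces are preserved — morphological terms like
    ``2-ranked`` or ``leaf blade`` are distinct surface forms, and stemming
    would merge terms that curators treat as different.
    """
    return surface.strip().lower()


def _iso(dt: datetime) -> str:
    return dt.isoformat()


def _from_iso(s: str) -> datetime:
    return datetime.fromisoformat(s)


# ---------------------------------------------------------------------------
# users, terms, concepts
# ---------------------------------------------------------------------------

@dataclass
class User:
    username: str
    role: str = "regular"
    external_ontology_id: Optional[str] = None

    @property
    def is_admin(self) -> bool:
        return self.role == "admin"

    def to_dict(self) -> dict:
        return {"username": self.username, "role": self.role,
                "external_ontology_id": self.external_ontology_id}

    @classmethod
    def from_dict(cls, d: dict) -> "User":
        return cls(d["username"], d.get("role", "regular"),
                   d.get("external_ontology_id"))


@dataclass
class Term:
    """A surface form plus the source sentences it was extracted from."""

    surface: str
    normalized: str
    #: list of (document label, sentence) pairs, insertion-ordered, unique.
    source_sentences: list = field(default_factory=list)

    def add_sentence(self, document: str, sentence: str) -> None:
        pair = (document, sentence)
        if pair not in self.source_sentences:
            self.source_sentences.append(pair)

    def documents(self) -> list:
        seen = []
        for doc, _ in self.source_sentences:
            if doc not in seen:
                seen.append(doc)
        return seen

    def to_dict(self) -> dict:
        return {"surface": self.surface, "normalized": self.normalized,
                "source_sentences": [list(p) for p in self.source_sentences]}

    @classmethod
    def from_dict(cls, d: dict) -> "Term":
        return cls(d["surface"], d["normalized"],
                   [tuple(p) for p in d.get("source_sentences", [])])


@dataclass(frozen=True)
class ConceptRecord:
    """A ⟨term, category, taxon group⟩ triple bound to a permanent UUID."""

    term: str
    category: str
    taxon_group: str
    uuid: str

    @property
    def triple(self):
        return (self.term, self.category, self.taxon_group)

    def to_dict(self) -> dict:
        return {"term": self.term, "category": self.category,
                "taxon_group": self.taxon_group, "uuid": self.uuid}

    @classmethod
    def from_dict(cls, d: dict) -> "ConceptRecord":
        return cls(d["term"], d["category"], d["taxon_group"], d["uuid"])


@dataclass
class ReferenceGlossary:
    """A read-only term → categories table used to pre-seed and approve
    categorizations (the local stand-in for an expert-reviewed system
    glossary)."""

    name: str
    taxon_group: str
    #: normalized term -> list of (category, definition-or-None)
    entries: dict = field(default_factory=dict)

    def categories_for(self, term: str) -> list:
        return [cat for cat, _ in self.entries.get(normalize_term(term), [])]

    def to_dict(self) -> dict:
        return {"name": self.name, "taxon_group": self.taxon_group,
                "entries": {t: [list(e) for e in es]
                            for t, es in self.entries.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceGlossary":
        return cls(d["name"], d["taxon_group"],
                   {t: [tuple(e) for e in es]
                    for t, es in d.get("entries", {}).items()})


# ---------------------------------------------------------------------------
# grouping task payload
# ---------------------------------------------------------------------------

@dataclass
class Category:
    name: str
    definition: Optional[str] = None
    origin: str = "user_created"  # imported_default | user_created | system_copied

    def to_dict(self) -> dict:
        return {"name": self.name, "definition": self.definition,
                "origin": self.origin}

    @classmethod
    def from_dict(cls, d: dict) -> "Category":
        return cls(d["name"], d.get("definition"), d.get("origin", "user_created"))


@dataclass
class Categorization:
    """One user's is_a decision for one term.

    ``current`` distinguishes the user's live decision set from superseded
    history; ``shadowed`` marks a decision hidden because the term was
    synonymized onto a preferred term in the same category (it reappears if
    the link is removed).
    """

    user: str
    term: str
    category: str
    timestamp: datetime
    accepted: bool = False
    current: bool = True
    shadowed: bool = False

    def to_dict(self) -> dict:
        return {"user": self.user, "term": self.term, "category": self.category,
                "timestamp": _iso(self.timestamp), "accepted": self.accepted,
                "current": self.current, "shadowed": self.shadowed}

    @classmethod
    def from_dict(cls, d: dict) -> "Categorization":
        return cls(d["user"], d["term"], d["category"],
                   _from_iso(d["timestamp"]), d.get("accepted", False),
                   d.get("current", True), d.get("shadowed", False))


@dataclass
class SynonymLink:
    user: str
    preferred: str
    synonym: str
    category: str
    timestamp: datetime
    accepted: bool = False
    active: bool = True

    @property
    def key(self):
        return (self.preferred, self.synonym, self.category)

    def to_dict(self) -> dict:
        return {"user": self.user, "preferred": self.preferred,
                "synonym": self.synonym, "category": self.category,
                "timestamp": _iso(self.timestamp), "accepted": self.accepted,
                "active": self.active}

    @classmethod
    def from_dict(cls, d: dict) -> "SynonymLink":
        return cls(d["user"], d["preferred"], d["synonym"], d["category"],
                   _from_iso(d["timestamp"]), d.get("accepted", False),
                   d.get("active", True))


@dataclass
class Comment:
    user: str
    term: str
    text: str
    timestamp: datetime

    def to_dict(self) -> dict:
        return {"user": self.user, "term": self.term, "text": self.text,
                "timestamp": _iso(self.timestamp)}

    @classmethod
    def from_dict(cls, d: dict) -> "Comment":
        return cls(d["user"], d["term"], d["text"], _from_iso(d["timestamp"]))


@dataclass
class GroupingData:
    categories: dict = field(default_factory=dict)   # name -> Category
    records: list = field(default_factory=list)      # [Categorization]
    links: list = field(default_factory=list)        # [SynonymLink]
    comments: list = field(default_factory=list)     # [Comment]
    #: approved decision keys: ["cat", term, category] or
    #: ["syn", preferred, synonym, category]
    accepted: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"categories": {n: c.to_dict() for n, c in self.categories.items()},
                "records": [r.to_dict() for r in self.records],
                "links": [l.to_dict() for l in self.links],
                "comments": [c.to_dict() for c in self.comments],
                "accepted": [list(k) for k in self.accepted]}

    @classmethod
    def from_dict(cls, d: dict) -> "GroupingData":
        return cls({n: Category.from_dict(c) for n, c in d.get("categories", {}).items()},
                   [Categorization.from_dict(r) for r in d.get("records", [])],
                   [SynonymLink.from_dict(l) for l in d.get("links", [])],
                   [Comment.from_dict(c) for c in d.get("comments", [])],
                   [tuple(k) for k in d.get("accepted", [])])


# ---------------------------------------------------------------------------
# hierarchy task payload
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    term: str
    saved: bool = False
    children: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"term": self.term, "saved": self.saved,
                "children": [c.to_dict() for c in self.children]}

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        return cls(d["term"], d.get("saved", False),
                   [TreeNode.from_dict(c) for c in d.get("children", [])])

    def copy(self) -> "TreeNode":
        return TreeNode(self.term, self.saved, [c.copy() for c in self.children])


@dataclass
class Placement:
    """A saved part_of decision: the root-to-term path in one user's tree."""

    user: str
    term: str
    path: tuple  # ordered terms, root first; path[-1] == term
    timestamp: datetime
    accepted: bool = False

    @property
    def path_string(self) -> str:
        return "-".join(self.path)

    def to_dict(self) -> dict:
        return {"user": self.user, "term": self.term, "path": list(self.path),
                "timestamp": _iso(self.timestamp), "accepted": self.accepted}

    @classmethod
    def from_dict(cls, d: dict) -> "Placement":
        return cls(d["user"], d["term"], tuple(d["path"]),
                   _from_iso(d["timestamp"]), d.get("accepted", False))


@dataclass
class HierarchyData:
    default_tree: Optional[TreeNode] = None
    trees: dict = field(default_factory=dict)        # user -> TreeNode
    placements: list = field(default_factory=list)   # [Placement]
    consumed: dict = field(default_factory=dict)     # user -> [terms]
    #: approved decision keys: ["path", term, *path]
    accepted: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"default_tree": self.default_tree.to_dict() if self.default_tree else None,
                "trees": {u: t.to_dict() for u, t in self.trees.items()},
                "placements": [p.to_dict() for p in self.placements],
                "consumed": {u: list(c) for u, c in self.consumed.items()},
                "accepted": [list(k) for k in self.accepted]}

    @classmethod
    def from_dict(cls, d: dict) -> "HierarchyData":
        dt = d.get("default_tree")
        return cls(TreeNode.from_dict(dt) if dt else None,
                   {u: TreeNode.from_dict(t) for u, t in d.get("trees", {}).items()},
                   [Placement.from_dict(p) for p in d.get("placements", [])],
                   {u: list(c) for u, c in d.get("consumed", {}).items()},
                   [tuple(k) for k in d.get("accepted", [])])


# ---------------------------------------------------------------------------
# ordering task payload
# ---------------------------------------------------------------------------

@dataclass
class Order:
    """One user's named arrangement of a term group into ordered boxes.

    ``boxes`` is the live edit state; ``saved_boxes`` is the last saved
    snapshot (the decision that participates in conflict detection and
    export).  ``order_id`` is a deterministic composite of the creating
    user, the group, and the creation-time name, so renaming keeps the id.
    """

    order_id: str
    name: str
    group: str
    user: str
    boxes: list = field(default_factory=list)        # list of [terms]
    saved_boxes: Optional[list] = None
    timestamp: Optional[datetime] = None
    accepted: bool = False

    def signature(self):
        """Hashable form of the saved sequence: tie membership and box order."""
        if self.saved_boxes is None:
            return None
        return tuple(frozenset(b) for b in self.saved_boxes)

    def to_dict(self) -> dict:
        return {"order_id": self.order_id, "name": self.name, "group": self.group,
                "user": self.user, "boxes": [list(b) for b in self.boxes],
                "saved_boxes": None if self.saved_boxes is None
                else [list(b) for b in self.saved_boxes],
                "timestamp": _iso(self.timestamp) if self.timestamp else None,
                "accepted": self.accepted}

    @classmethod
    def from_dict(cls, d: dict) -> "Order":
        return cls(d["order_id"], d["name"], d["group"], d["user"],
                   [list(b) for b in d.get("boxes", [])],
                   None if d.get("saved_boxes") is None
                   else [list(b) for b in d["saved_boxes"]],
                   _from_iso(d["timestamp"]) if d.get("timestamp") else None,
                   d.get("accepted", False))


@dataclass
class OrderingData:
    groups: dict = field(default_factory=dict)   # name -> [terms]
    orders: list = field(default_factory=list)   # [Order]
    #: approved decision keys: ["order", group, name, serialized signature]
    accepted: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"groups": {n: list(t) for n, t in self.groups.items()},
                "orders": [o.to_dict() for o in self.orders],
                "accepted": [list(k) for k in self.accepted]}

    @classmethod
    def from_dict(cls, d: dict) -> "OrderingData":
        return cls({n: list(t) for n, t in d.get("groups", {}).items()},
                   [Order.from_dict(o) for o in d.get("orders", [])],
                   [tuple(k) for k in d.get("accepted", [])])


# ---------------------------------------------------------------------------
# term sets, versions, datasets
# ---------------------------------------------------------------------------

_DATA_TYPES = {"grouping": GroupingData, "hierarchy": HierarchyData,
               "ordering": OrderingData}


@dataclass
class GlossaryVersion:
    """An immutable released snapshot of a finalized term set."""

    task: str
    version: tuple            # (major, minor)
    release_date: datetime
    participants: list
    dataset_name: str
    taxon_group: str
    content: dict

    @property
    def version_string(self) -> str:
        return f"v{self.version[0]}.{self.version[1]}"

    def to_dict(self) -> dict:
        return {"task": self.task, "version": list(self.version),
                "release_date": _iso(self.release_date),
                "participants": list(self.participants),
                "dataset_name": self.dataset_name,
                "taxon_group": self.taxon_group, "content": self.content}

    @classmethod
    def from_dict(cls, d: dict) -> "GlossaryVersion":
        return cls(d["task"], tuple(d["version"]), _from_iso(d["release_date"]),
                   list(d["participants"]), d["dataset_name"],
                   d["taxon_group"], d["content"])


@dataclass
class TermSet:
    task: str
    status: str = "open"              # open | finalized
    version: tuple = (0, 0)           # (major, minor)
    terms: dict = field(default_factory=dict)   # normalized -> Term
    touched: bool = False
    data: object = None
    versions: list = field(default_factory=list)  # [GlossaryVersion]

    def __post_init__(self):
        if self.data is None:
            self.data = _DATA_TYPES[self.task]()

    @property
    def is_open(self) -> bool:
        return self.status == "open"

    def get_term(self, term: str) -> Optional[Term]:
        return self.terms.get(normalize_term(term))

    def to_dict(self) -> dict:
        return {"task": self.task, "status": self.status,
                "version": list(self.version),
                "terms": {n: t.to_dict() for n, t in self.terms.items()},
                "touched": self.touched, "data": self.data.to_dict(),
                "versions": [v.to_dict() for v in self.versions]}

    @classmethod
    def from_dict(cls, d: dict) -> "TermSet":
        return cls(d["task"], d.get("status", "open"), tuple(d.get("version", (0, 0))),
                   {n: Term.from_dict(t) for n, t in d.get("terms", {}).items()},
                   d.get("touched", False),
                   _DATA_TYPES[d["task"]].from_dict(d.get("data", {})),
                   [GlossaryVersion.from_dict(v) for v in d.get("versions", [])])


@dataclass
class Dataset:
    name: str
    taxon_group: str
    owner: str                       # username
    visibility: str = "public"
    term_sets: dict = field(default_factory=dict)   # task -> TermSet
    source_documents: list = field(default_factory=list)
    merged_from: list = field(default_factory=list)  # provenance of merges

    def to_dict(self) -> dict:
        return {"name": self.name, "taxon_group": self.taxon_group,
                "owner": self.owner, "visibility": self.visibility,
                "term_sets": {t: ts.to_dict() for t, ts in self.term_sets.items()},
                "source_documents": list(self.source_documents),
                "merged_from": list(self.merged_from)}

    @classmethod
    def from_dict(cls, d: dict) -> "Dataset":
        return cls(d["name"], d["taxon_group"], d["owner"],
                   d.get("visibility", "public"),
                   {t: TermSet.from_dict(ts) for t, ts in d.get("term_sets", {}).items()},
                   list(d.get("source_documents", [])),
                   list(d.get("merged_from", [])))


@dataclass
class TermSetStats:
    """Curation statistics for a grouping term set."""

    unique_terms: int = 0
    users: int = 0
    categorizations: int = 0
    conflict_categorizations: int = 0
    comments: int = 0
    concepts: int = 0
    multi_category_terms: int = 0
    conflict_rate: float = 0.0    # percentage, one decimal

    def to_dict(self) -> dict:
        return {"unique_terms": self.unique_terms, "users": self.users,
                "categorizations": self.categorizations,
                "conflict_categorizations": self.conflict_categorizations,
                "comments": self.comments, "concepts": self.concepts,
                "multi_category_terms": self.multi_category_terms,
                "conflict_rate": self.conflict_rate}
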