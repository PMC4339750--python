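"""The Structure Hierarchy workflow: per-user part_of trees.

Every user edits a private copy of a shared default tree (e.g. the root
``plant`` with its organs).  Terms are dragged in as child nodes; a term
may label several nodes ("many structures may have a base"), and saving
turns every new node into a timestamped placement — the root-to-term path
that is the unit of decision, conflict detection, and export.

Paths are stored as ordered term lists.  The hyphen-joined rendering
(``plant-flower-stamen-anther``) is derived output only and is never
parsed back, because structure terms may themselves contain hyphens.
"""
from __future__ import annotations

from typing import Optional

from .errors import (CycleError, FrozenTermSetError, InvalidOperation,
                     UnknownName)
from .model import (SYSTEM_USER, HierarchyData, Placement, TermSet, TreeNode,
                    normalize_term)


def _username(user) -> str:
    return user if isinstance(user, str) else user.username


def _require_open(term_set: TermSet) -> None:
    if not term_set.is_open:
        raise FrozenTermSetError("term set is finalized; decisions are frozen")


# ---------------------------------------------------------------------------
# default tree
# ---------------------------------------------------------------------------

def tree_from_paths(paths, saved: bool = True) -> TreeNode:
    """Build a tree from root-to-node paths (each a list of terms).

    All paths must share one root.  Missing intermediate nodes are created
    implicitly, so ``[["plant", "flower", "stamen"]]`` yields a three-level
    chain.
    """
    norm = [[normalize_term(t) for t in p] for p in paths if p]
    if not norm:
        raise InvalidOperation("no paths given")
    roots = {p[0] for p in norm}
    if len(roots) != 1:
        raise InvalidOperation(f"default paths must share one root, got {sorted(roots)}")
    for p in norm:
        if len(set(p)) != len(p):
            raise CycleError(f"path {p} repeats a term (cycle)")
    root = TreeNode(term=norm[0][0], saved=saved)
    for p in norm:
        node = root
        for term in p[1:]:
            child = next((c for c in node.children if c.term == term), None)
            if child is None:
                child = TreeNode(term=term, saved=saved)
                node.children.append(child)
            node = child
    return root


def init_hierarchy(term_set: TermSet, default_paths,
                   taxon_group: Optional[str] = None) -> TreeNode:
    """Install the shared default tree every user starts from.

    Default nodes are attributed to the reserved ``system`` user and are
    saved from the start (they carry no removable "x").  With no default
    paths, a single implicit root named after the taxon group is used.
    """
    _require_open(term_set)
    data: HierarchyData = term_set.data
    if default_paths:
        data.default_tree = tree_from_paths(default_paths, saved=True)
    else:
        if not taxon_group:
            raise InvalidOperation("empty defaults need a taxon group for the root")
        data.default_tree = TreeNode(term=normalize_term(taxon_group), saved=True)
    data.trees = {}
    return data.default_tree


def user_tree(term_set: TermSet, user) -> TreeNode:
    """The user's editable tree, created from the default tree on first use."""
    username = _username(user)
    data: HierarchyData = term_set.data
    if data.default_tree is None:
        raise InvalidOperation("hierarchy not initialized")
    if username not in data.trees:
        data.trees[username] = data.default_tree.copy()
        data.consumed.setdefault(username, [])
    return data.trees[username]


def resolve(root: TreeNode, path) -> TreeNode:
    """Resolve a root-to-node path (list of terms) to its node."""
    path = [normalize_term(t) for t in path]
    if not path or path[0] != root.term:
        raise UnknownName(f"path {path} does not start at root {root.term!r}")
    node = root
    for term in path[1:]:
        nxt = next((c for c in node.children if c.term == term), None)
        if nxt is None:
            raise UnknownName(f"path {path} does not resolve (missing {term!r})")
        node = nxt
    return node


def node_path(root: TreeNode, target: TreeNode):
    """Root-to-node path of a node object, or None if not in the tree."""
    def walk(node, acc):
        acc = acc + [node.term]
        if node is target:
            return acc
        for c in node.children:
            found = walk(c, acc)
            if found:
                return found
        return None
    return walk(root, [])


def pending_terms(term_set: TermSet, user) -> list:
    """Terms still available for placement by this user."""
    username = _username(user)
    consumed = set(term_set.data.consumed.get(username, []))
    return [t for t in term_set.terms if t not in consumed]


def add_child(ws, term_set: TermSet, user, term: str, parent_path,
              keep_in_list: bool = False) -> TreeNode:
    """Create an unsaved child node under ``parent_path`` in the user's tree.

    With ``keep_in_list`` the term stays available for further placements
    (reuse); otherwise it is consumed from the pending list.  A node is
    never its own ancestor: adding a term that already occurs on the path
    from the root to the parent is refused.
    """
    _require_open(term_set)
    username = _username(user)
    key = normalize_term(term)
    if key not in term_set.terms:
        raise UnknownName(f"term {term!r} is not in this term set")
    if key in set(term_set.data.consumed.get(username, [])):
        raise InvalidOperation(
            f"term {term!r} was already placed; re-place it with keep_in_list")
    root = user_tree(term_set, user)
    parent = resolve(root, parent_path)
    chain = [normalize_term(t) for t in parent_path]
    if key in chain:
        raise CycleError(
            f"{term!r} is an ancestor of the target node; a node cannot be "
            "its own ancestor")
    if any(c.term == key for c in parent.children):
        raise InvalidOperation(
            f"{term!r} is already a child of {parent.term!r}")
    node = TreeNode(term=key, saved=False)
    parent.children.append(node)
    if not keep_in_list:
        term_set.data.consumed.setdefault(username, []).append(key)
    term_set.touched = True
    return node


def remove_unsaved(ws, term_set: TermSet, user, path) -> list:
    """Remove an unsaved node (and its unsaved subtree); consumed terms
    return to the pending list.  Saved nodes cannot be removed."""
    _require_open(term_set)
    username = _username(user)
    root = user_tree(term_set, user)
    path = [normalize_term(t) for t in path]
    node = resolve(root, path)
    if node.saved:
        raise InvalidOperation("saved nodes cannot be removed")
    if node is root:
        raise InvalidOperation("cannot remove the root")
    parent = resolve(root, path[:-1])
    parent.children.remove(node)
    removed = []

    def collect(n):
        removed.append(n.term)
        for c in n.children:
            collect(c)

    collect(node)
    consumed = term_set.data.consumed.setdefault(username, [])
    for t in removed:
        if t in consumed:
            consumed.remove(t)
    return removed


def save_hierarchy(ws, term_set: TermSet, user) -> list:
    """Turn every unsaved node in the user's tree into a placement."""
    _require_open(term_set)
    username = _username(user)
    root = user_tree(term_set, user)
    new = []

    def walk(node, acc):
        acc = acc + [node.term]
        if not node.saved:
            node.saved = True
            p = Placement(user=username, term=node.term, path=tuple(acc),
                          timestamp=ws.clock())
            term_set.data.placements.append(p)
            new.append(p)
        for c in node.children:
            walk(c, acc)

    walk(root, [])
    if new:
        term_set.touched = True
    return new


def path_string(placement_or_path) -> str:
    """Hyphen-joined rendering of a root-to-term path."""
    if isinstance(placement_or_path, Placement):
        return placement_or_path.path_string
    return "-".join(placement_or_path)


def saved_paths(term_set: TermSet, user: str, term: Optional[str] = None) -> set:
    return {p.path for p in term_set.data.placements
            if p.user == user and (term is None or p.term == term)}


def detect_conflicts(term_set: TermSet) -> set:
    """Terms for which at least two users hold non-identical sets of saved
    paths.  Multi-placement is legitimate: two users who both placed
    ``base`` under the same two parents do not conflict."""
    by_term: dict[str, dict[str, set]] = {}
    for p in term_set.data.placements:
        by_term.setdefault(p.term, {}).setdefault(p.user, set()).add(p.path)
    conflicted = set()
    for term, per_user in by_term.items():
        if len(per_user) >= 2 and len({frozenset(s) for s in per_user.values()}) > 1:
            conflicted.add(term)
    return conflicted


def canonical(node: TreeNode):
    """Order-free structural form of a tree.  Sibling order is insertion
    order for display, but part_of semantics is order-free, so equality
    checks go through this form."""
    return (node.term, frozenset(canonical(c) for c in node.children))


def trees_equal(a: TreeNode, b: TreeNode) -> bool:
    return canonical(a) == canonical(b)


def render(root: TreeNode, indent: str = "  ") -> str:
    """Indented text rendering of a tree (for `hier show`)."""
    lines = []

    def walk(node, depth):
        marker = "" if node.saved else " *"
        lines.append(f"{indent * depth}{node.term}{marker}")
        for c in node.children:
            walk(c, depth + 1)

    walk(root, 0)
    return "\n".join(lines)
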