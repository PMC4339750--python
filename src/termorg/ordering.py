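"""The Term Order workflow: ranked categorical descriptor states.

Character-state terms that fall in a natural order (colors by wavelength,
hairiness from glabrous to tomentose, orientation from prostrate to erect)
are arranged into named orders.  An order is a sequence of *boxes*; terms
judged equivalent share a box (a tie).  Serialization assigns each term an
integer distance equal to its box index counted from zero, so tied terms
share a distance and an order of N terms always yields exactly N rows.

Orders are per-user decisions: the same group may carry several orders
(hue vs. saturation for colors), and two users' saves of the same-named
order are compared box-for-box for conflict detection.
"""
from __future__ import annotations

import copy
from typing import Optional

from .errors import (DuplicateName, FrozenTermSetError, InvalidOperation,
                     UnknownName)
from .model import Order, OrderingData, TermSet, normalize_term


def _username(user) -> str:
    return user if isinstance(user, str) else user.username


def _require_open(term_set: TermSet) -> None:
    if not term_set.is_open:
        raise FrozenTermSetError("term set is finalized; decisions are frozen")


def make_order_id(user: str, group: str, name: str) -> str:
    """Deterministic order identifier.

    Composed from the creating user, the term group, and the creation-time
    name, so renaming an order keeps its id.  The id is unique per logical
    order but repeats across the serialized rows of that order.
    """
    return f"{user}|{group}|{name}"


def get_group(term_set: TermSet, group: str) -> list:
    data: OrderingData = term_set.data
    if group not in data.groups:
        raise UnknownName(f"unknown term group {group!r}")
    return data.groups[group]


def create_group(term_set: TermSet, name: str, members=()) -> list:
    _require_open(term_set)
    data: OrderingData = term_set.data
    if name in data.groups:
        raise DuplicateName(f"term group {name!r} already exists")
    data.groups[name] = [normalize_term(m) for m in members]
    return data.groups[name]


def add_term_to_group(term_set: TermSet, group: str, term: str) -> None:
    """Make a new term available for placement in any order of the group."""
    _require_open(term_set)
    members = get_group(term_set, group)
    key = normalize_term(term)
    if key in members:
        raise DuplicateName(f"{term!r} is already in group {group!r}")
    members.append(key)
    term_set.touched = True


def create_order(ws, term_set: TermSet, user, group: str, name: str) -> Order:
    _require_open(term_set)
    username = _username(user)
    get_group(term_set, group)
    data: OrderingData = term_set.data
    if any(o.user == username and o.group == group and o.name == name
           for o in data.orders):
        raise DuplicateName(
            f"order {name!r} already exists for {username!r} in {group!r}")
    order = Order(order_id=make_order_id(username, group, name),
                  name=name, group=group, user=username)
    data.orders.append(order)
    term_set.touched = True
    return order


def get_order(term_set: TermSet, user, group: str, name: str) -> Order:
    username = _username(user)
    for o in term_set.data.orders:
        if o.user == username and o.group == group and o.name == name:
            return o
    raise UnknownName(f"no order {name!r} for {username!r} in group {group!r}")


def rename_order(ws, term_set: TermSet, user, order: Order,
                 new_name: str) -> None:
    """Rename an owned order; the order id is unchanged."""
    _require_open(term_set)
    username = _username(user)
    if order.user != username:
        raise InvalidOperation("only the order's creator may rename it")
    if any(o.user == username and o.group == order.group and o.name == new_name
           and o is not order for o in term_set.data.orders):
        raise DuplicateName(f"order {new_name!r} already exists")
    order.name = new_name
    term_set.touched = True


def place(ws, term_set: TermSet, user, order: Order, term: str,
          box_index: int, new_box: bool = False) -> None:
    """Put a term into a box of an order.

    With ``new_box`` a fresh box is inserted at ``box_index``; otherwise
    the term joins the existing box there (a tie).  A term placed before
    is moved, so it occupies at most one box; boxes emptied by a move are
    dropped.
    """
    _require_open(term_set)
    if _username(user) != order.user:
        raise InvalidOperation("orders are edited by their creator only")
    key = normalize_term(term)
    if key not in get_group(term_set, order.group):
        raise UnknownName(f"{term!r} is not in group {order.group!r}")
    for box in order.boxes:
        if key in box:
            box.remove(key)
    order.boxes = [b for b in order.boxes if b]
    if new_box:
        if box_index > len(order.boxes) or box_index < 0:
            raise InvalidOperation(f"box index {box_index} out of range")
        order.boxes.insert(box_index, [key])
    else:
        if box_index >= len(order.boxes) or box_index < 0:
            raise InvalidOperation(f"box index {box_index} out of range")
        order.boxes[box_index].append(key)
    term_set.touched = True


def append_sequence(ws, term_set: TermSet, user, order: Order, terms) -> None:
    """Convenience: append each term as its own new box, in the given order."""
    for t in terms:
        place(ws, term_set, user, order, t, len(order.boxes), new_box=True)


def save_orders(ws, term_set: TermSet, user) -> list:
    """Snapshot the user's edited orders as timestamped decisions."""
    _require_open(term_set)
    username = _username(user)
    saved = []
    for order in term_set.data.orders:
        if order.user != username or not order.boxes:
            continue
        if order.saved_boxes == order.boxes:
            continue
        order.saved_boxes = copy.deepcopy(order.boxes)
        order.timestamp = ws.clock()
        saved.append(order)
    if saved:
        term_set.touched = True
    return saved


def serialize_order(order: Order) -> list:
    """One row per term: (order_id, order_name, term, distance), with
    distance = the term's box index counted from zero; rows sorted by
    distance then term."""
    if order.saved_boxes is None:
        raise InvalidOperation(f"order {order.name!r} has never been saved")
    rows = []
    for distance, box in enumerate(order.saved_boxes):
        for term in sorted(box):
            rows.append({"order_id": order.order_id, "order_name": order.name,
                         "term": term, "distance": distance,
                         "user": order.user, "timestamp": order.timestamp})
    rows.sort(key=lambda r: (r["distance"], r["term"]))
    return rows


def detect_conflicts(term_set: TermSet) -> set:
    """Names of orders for which at least two users saved non-identical
    box sequences (same boxes, same order, same tie membership)."""
    by_name: dict[tuple, dict[str, tuple]] = {}
    for o in term_set.data.orders:
        sig = o.signature()
        if sig is not None:
            by_name.setdefault((o.group, o.name), {})[o.user] = sig
    conflicted = set()
    for (group, name), per_user in by_name.items():
        if len(per_user) >= 2 and len(set(per_user.values())) > 1:
            conflicted.add(name)
    return conflicted
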