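"""Readers and writers for the glossary file formats and import bundles.

A finalized grouping term set is released as two CSV files,
``<dataset>_term_category.csv`` and ``<dataset>_syns.csv``.  Both open
with ``*``-prefixed comment lines carrying the version number, release
date, and participant names; the term_category file additionally closes
with ``*``-prefixed natural-language category definitions.  Data rows are
RFC 4180 CSV (UTF-8, LF, header row) sorted by (category, term) so a
given release is byte-stable.

term_category columns: ``term, category, hasSyn, sourceDataset, termID``.
The termID is the permanent UUID of the ⟨term, category⟩ concept;
``hasSyn`` is 1 exactly when the syns file carries rows for that concept,
and synonym terms never appear in the term column.  syns columns:
``term, category, termID, synonym`` — one row per synonym, all sharing
the preferred pair's termID (a UUID never identifies a synonym).

Finalized ordering and hierarchy term sets export as single tables:
``orderID, orderName, term, distance, accepted, userid, confirmDate`` and
``term, pathWithName, accepted, userid, confirmDate``.
"""
from __future__ import annotations

import csv
import io
import json
import uuid as uuidlib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InvalidOperation, ValidationError
from .model import GlossaryVersion, Term, normalize_term

TERM_CATEGORY_COLUMNS = ["term", "category", "hasSyn", "sourceDataset", "termID"]
SYNS_COLUMNS = ["term", "category", "termID", "synonym"]
ORDER_COLUMNS = ["orderID", "orderName", "term", "distance", "accepted",
                 "userid", "confirmDate"]
PATHS_COLUMNS = ["term", "pathWithName", "accepted", "userid", "confirmDate"]

_DOC_JOIN = "; "


# ---------------------------------------------------------------------------
# glossary writing
# ---------------------------------------------------------------------------

def _metadata_lines(version: GlossaryVersion) -> list:
    return [
        f"* glossary: {version.dataset_name}",
        f"* version: {version.version_string}",
        f"* release_date: {version.release_date.isoformat()}",
        f"* participants: {'; '.join(version.participants)}",
    ]


def _csv_line(row) -> str:
    buf = io.StringIO()
    csv.writer(buf, lineterminator="\n").writerow(row)
    return buf.getvalue().rstrip("\n")


def write_glossary(version: GlossaryVersion, dataset_name: str, directory):
    """Write the term_category and syns files for a finalized grouping
    version; returns the two paths."""
    if version.task != "grouping":
        raise InvalidOperation("glossary files are produced from grouping term sets")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = _metadata_lines(version)
    concepts = sorted(version.content.get("concepts", []),
                      key=lambda c: (c["category"], c["term"]))
    synonyms = sorted(version.content.get("synonyms", []),
                      key=lambda s: (s["category"], s["preferred"], s["synonym"]))

    tc_lines = list(meta)
    tc_lines.append(_csv_line(TERM_CATEGORY_COLUMNS))
    for c in concepts:
        tc_lines.append(_csv_line([
            c["term"], c["category"], 1 if c["has_syn"] else 0,
            _DOC_JOIN.join(c.get("source_datasets", [])), c["uuid"]]))
    for name, definition in sorted(
            version.content.get("category_definitions", {}).items()):
        tc_lines.append(f"* category: {name}: {definition}")

    syns_lines = list(meta)
    syns_lines.append(_csv_line(SYNS_COLUMNS))
    for s in synonyms:
        syns_lines.append(_csv_line([s["preferred"], s["category"],
                                     s["uuid"], s["synonym"]]))

    tc_path = directory / f"{dataset_name}_term_category.csv"
    syns_path = directory / f"{dataset_name}_syns.csv"
    tc_path.write_text("\n".join(tc_lines) + "\n", encoding="utf-8")
    syns_path.write_text("\n".join(syns_lines) + "\n", encoding="utf-8")
    return tc_path, syns_path


# ---------------------------------------------------------------------------
# glossary reading
# ---------------------------------------------------------------------------

def _split_file(path: Path):
    """Separate a glossary file into (metadata dict, data lines, trailing
    comment lines)."""
    lines = path.read_text(encoding="utf-8").splitlines()
    meta = {}
    i = 0
    while i < len(lines) and lines[i].startswith("*"):
        body = lines[i].lstrip("*").strip()
        key, _, value = body.partition(": ")
        meta[key] = value
        i += 1
    data = []
    trailing = []
    for line in lines[i:]:
        if line.startswith("*"):
            trailing.append(line)
        elif line.strip():
            if trailing:
                raise ValidationError(f"{path}: data row after comment block")
            data.append(line)
    return meta, data, trailing


def _parse_rows(path: Path, data_lines, expected_columns):
    rows = list(csv.reader(data_lines))
    if not rows:
        raise ValidationError(f"{path}: missing header row")
    header = rows[0]
    if header != expected_columns:
        raise ValidationError(
            f"{path}: expected columns {expected_columns}, found {header}")
    out = []
    for r in rows[1:]:
        if len(r) != len(expected_columns):
            raise ValidationError(f"{path}: malformed row {r}")
        out.append(dict(zip(expected_columns, r)))
    return out


def _check_uuid(value: str, path: Path) -> str:
    try:
        return str(uuidlib.UUID(value))
    except (ValueError, AttributeError):
        raise ValidationError(f"{path}: malformed UUID {value!r}") from None


def read_glossary(term_category_path, syns_path) -> GlossaryVersion:
    """Parse and cross-validate a released glossary pair.

    Raises :class:`~termorg.errors.ValidationError` on schema violations:
    wrong or missing columns, duplicate ⟨term, category⟩ rows, malformed
    UUIDs, ``hasSyn`` flags inconsistent with the syns file, or synonym
    terms leaking into the term column.
    """
    from datetime import datetime

    tc_path, syns_path = Path(term_category_path), Path(syns_path)
    meta, tc_data, trailing = _split_file(tc_path)
    smeta, syns_data, _ = _split_file(syns_path)
    tc_rows = _parse_rows(tc_path, tc_data, TERM_CATEGORY_COLUMNS)
    syns_rows = _parse_rows(syns_path, syns_data, SYNS_COLUMNS)

    synonyms = []
    syn_pairs = set()
    syn_terms = set()
    for r in syns_rows:
        uuid = _check_uuid(r["termID"], syns_path)
        synonyms.append({"preferred": r["term"], "category": r["category"],
                         "uuid": uuid, "synonym": r["synonym"]})
        syn_pairs.add((r["term"], r["category"]))
        syn_terms.add((r["synonym"], r["category"]))

    concepts = []
    seen = set()
    for r in tc_rows:
        pair = (r["term"], r["category"])
        if pair in seen:
            raise ValidationError(f"{tc_path}: duplicate concept row {pair}")
        seen.add(pair)
        if pair in syn_terms:
            raise ValidationError(
                f"{tc_path}: {pair} appears as a synonym in the syns file")
        if r["hasSyn"] not in ("0", "1"):
            raise ValidationError(f"{tc_path}: hasSyn must be 0 or 1, got {r['hasSyn']!r}")
        has_syn = r["hasSyn"] == "1"
        if has_syn != (pair in syn_pairs):
            raise ValidationError(
                f"{tc_path}: hasSyn={r['hasSyn']} inconsistent with syns file "
                f"for {pair}")
        uuid = _check_uuid(r["termID"], tc_path)
        concepts.append({"term": r["term"], "category": r["category"],
                         "uuid": uuid, "has_syn": has_syn,
                         "source_datasets": [d for d in
                                             r["sourceDataset"].split(_DOC_JOIN)
                                             if d]})

    defs = {}
    for line in trailing:
        if not line.startswith("* category: "):
            continue
        rest = line[len("* category: "):]
        name, sep, definition = rest.partition(": ")
        if not sep:
            raise ValidationError(f"{tc_path}: malformed definition line {line!r}")
        defs[name] = definition

    for key in ("glossary", "version", "release_date"):
        if key not in meta:
            raise ValidationError(f"{tc_path}: missing metadata line {key!r}")
    try:
        major, minor = meta["version"].lstrip("v").split(".")
        version = (int(major), int(minor))
    except ValueError:
        raise ValidationError(
            f"{tc_path}: malformed version {meta['version']!r}") from None
    participants = [p for p in meta.get("participants", "").split("; ") if p]
    return GlossaryVersion(
        task="grouping", version=version,
        release_date=datetime.fromisoformat(meta["release_date"]),
        participants=participants, dataset_name=meta["glossary"],
        taxon_group="", content={"concepts": concepts, "synonyms": synonyms,
                                 "category_definitions": defs})


# ---------------------------------------------------------------------------
# order and paths tables
# ---------------------------------------------------------------------------

def write_order_table(version: GlossaryVersion, path):
    """Write the finalized ordering rows; accepted is always 1 because only
    accepted orders are exported."""
    if version.task != "ordering":
        raise InvalidOperation("order tables are produced from ordering term sets")
    path = Path(path)
    lines = _metadata_lines(version)
    lines.append(_csv_line(ORDER_COLUMNS))
    for r in version.content.get("rows", []):
        lines.append(_csv_line([r["order_id"], r["order_name"], r["term"],
                                r["distance"], 1, r["userid"],
                                r["confirm_date"]]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_paths_table(version: GlossaryVersion, path):
    """Write the finalized part_of placements with hyphen-joined paths."""
    if version.task != "hierarchy":
        raise InvalidOperation("paths tables are produced from hierarchy term sets")
    path = Path(path)
    lines = _metadata_lines(version)
    lines.append(_csv_line(PATHS_COLUMNS))
    for p in version.content.get("placements", []):
        lines.append(_csv_line([p["term"], "-".join(p["path"]), 1,
                                p["userid"], p["confirm_date"]]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_table(path, expected_columns):
    """Read an order or paths table back into a list of row dicts."""
    _, data, _ = _split_file(Path(path))
    return _parse_rows(Path(path), data, expected_columns)


# ---------------------------------------------------------------------------
# import bundles
# ---------------------------------------------------------------------------

@dataclass
class ImportBundle:
    """Parsed form of an import-bundle directory.

    Layout: ``manifest.txt`` (``key: value`` lines — name, taxon_group,
    visibility, owner) plus optional per-task files: ``terms_grouping.csv``
    (term, category), ``terms_hierarchy.csv`` (term),
    ``terms_order.csv`` (group_name, term), ``hierarchy_defaults.txt``
    (one hyphen-joined root-to-node path per line),
    ``categories.csv`` (category, definition), and ``sentences.csv``
    (term, document, sentence).
    """

    name: str
    taxon_group: str
    visibility: str = "public"
    owner: str = ""
    grouping_terms: list = field(default_factory=list)       # [Term]
    preassigned: dict = field(default_factory=dict)          # term -> category
    default_categories: list = field(default_factory=list)   # [(name, def)]
    hierarchy_terms: list = field(default_factory=list)      # [Term]
    hierarchy_defaults: list = field(default_factory=list)   # [[terms]]
    order_groups: dict = field(default_factory=dict)         # group -> [terms]
    sentences: list = field(default_factory=list)            # [(term, doc, sent)]


def _read_csv(path: Path, expected_header) -> list:
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0] != expected_header:
        raise ValidationError(
            f"{path}: expected header {expected_header}, got "
            f"{rows[0] if rows else 'empty file'}")
    return rows[1:]


def read_import_bundle(directory) -> ImportBundle:
    directory = Path(directory)
    manifest = directory / "manifest.txt"
    if not manifest.exists():
        raise ValidationError(f"missing manifest: {manifest}")
    fields = {}
    for line in manifest.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        key, sep, value = line.partition(":")
        if not sep:
            raise ValidationError(f"{manifest}: malformed line {line!r}")
        fields[key.strip()] = value.strip()
    for required in ("name", "taxon_group"):
        if required not in fields:
            raise ValidationError(f"{manifest}: missing field {required!r}")
    bundle = ImportBundle(name=fields["name"], taxon_group=fields["taxon_group"],
                          visibility=fields.get("visibility", "public"),
                          owner=fields.get("owner", ""))

    sentences_by_term: dict[str, list] = {}
    sents = directory / "sentences.csv"
    if sents.exists():
        for term, doc, sentence in _read_csv(sents, ["term", "document", "sentence"]):
            bundle.sentences.append((term, doc, sentence))
            sentences_by_term.setdefault(normalize_term(term), []).append(
                (doc, sentence))

    def make_term(surface: str) -> Term:
        key = normalize_term(surface)
        return Term(surface, key, list(sentences_by_term.get(key, [])))

    tg = directory / "terms_grouping.csv"
    if tg.exists():
        for row in _read_csv(tg, ["term", "category"]):
            term, category = row
            bundle.grouping_terms.append(make_term(term))
            if category:
                bundle.preassigned[normalize_term(term)] = category
    th = directory / "terms_hierarchy.csv"
    if th.exists():
        for (term,) in _read_csv(th, ["term"]):
            bundle.hierarchy_terms.append(make_term(term))
    to = directory / "terms_order.csv"
    if to.exists():
        for group, term in _read_csv(to, ["group_name", "term"]):
            bundle.order_groups.setdefault(group, []).append(term)
    cats = directory / "categories.csv"
    if cats.exists():
        for name, definition in _read_csv(cats, ["category", "definition"]):
            bundle.default_categories.append((name, definition or None))
    defaults = directory / "hierarchy_defaults.txt"
    if defaults.exists():
        for line in defaults.read_text(encoding="utf-8").splitlines():
            if line.strip():
                bundle.hierarchy_defaults.append(line.strip().split("-"))
    return bundle


def write_import_bundle(bundle: ImportBundle, directory) -> Path:
    """Serialize an ImportBundle to a bundle directory (inverse of
    :func:`read_import_bundle`; used by the fixture generator)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "manifest.txt").write_text(
        f"name: {bundle.name}\ntaxon_group: {bundle.taxon_group}\n"
        f"visibility: {bundle.visibility}\nowner: {bundle.owner}\n",
        encoding="utf-8")

    def dump(name, header, rows):
        with (directory / name).open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(header)
            w.writerows(rows)

    if bundle.grouping_terms:
        dump("terms_grouping.csv", ["term", "category"],
             [[t.surface, bundle.preassigned.get(t.normalized, "")]
              for t in bundle.grouping_terms])
    if bundle.hierarchy_terms:
        dump("terms_hierarchy.csv", ["term"],
             [[t.surface] for t in bundle.hierarchy_terms])
    if bundle.order_groups:
        dump("terms_order.csv", ["group_name", "term"],
             [[g, t] for g, terms in bundle.order_groups.items() for t in terms])
    if bundle.default_categories:
        dump("categories.csv", ["category", "definition"],
             [[n, d or ""] for n, d in bundle.default_categories])
    if bundle.sentences:
        dump("sentences.csv", ["term", "document", "sentence"], bundle.sentences)
    if bundle.hierarchy_defaults:
        (directory / "hierarchy_defaults.txt").write_text(
            "\n".join("-".join(p) for p in bundle.hierarchy_defaults) + "\n",
            encoding="utf-8")
    return directory


def load_bundle(ws, bundle: ImportBundle):
    """Create a dataset from a bundle and import its term sets."""
    owner = bundle.owner or "importer"
    if owner not in ws.users:
        ws.add_user(owner)
    ds = ws.create_dataset(bundle.name, bundle.taxon_group, owner,
                           bundle.visibility)
    if bundle.grouping_terms:
        ts = ws.import_term_set(ds, "grouping", bundle.grouping_terms,
                                default_categories=bundle.default_categories)
        from . import grouping
        for term, category in bundle.preassigned.items():
            if category not in ts.data.categories:
                from .model import Category
                ts.data.categories[category] = Category(
                    category, origin="imported_default")
            grouping.assign(ws, ts, owner, [term], category)
    if bundle.hierarchy_terms or bundle.hierarchy_defaults:
        terms = bundle.hierarchy_terms or bundle.grouping_terms
        ws.import_term_set(ds, "hierarchy", terms,
                           default_paths=bundle.hierarchy_defaults)
    if bundle.order_groups:
        all_terms = [Term(t, normalize_term(t))
                     for terms in bundle.order_groups.values() for t in terms]
        ws.import_term_set(ds, "ordering", all_terms,
                           term_groups=bundle.order_groups)
    return ds
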