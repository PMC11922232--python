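"""Concept schema: classes, attributes, surface-form dictionaries, and the
inclusion / exclusion / false-positive term lists.

A :class:`Lexicon` is the single configuration object consumed by every
other stage. Surface forms and term lists are stored *post-normalization*
(see :func:`hlner.preprocess.normalize`) so the dictionary and the post text
live in the same space. The bundled Hodgkin's-lymphoma schema ships as a
YAML file under ``hlner/data/`` and is loaded by :func:`builtin_hl_lexicon`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import yaml

from .preprocess import normalize

__all__ = [
    "ConceptClass",
    "AttributeDef",
    "Lexicon",
    "LexiconFormatError",
    "LexiconValidationError",
    "load_lexicon",
    "save_lexicon",
    "validate_lexicon",
    "builtin_hl_lexicon",
]

_BUILTIN_RESOURCE = "hodgkin_lexicon.yaml"


class LexiconFormatError(ValueError):
    """Raised when a lexicon config file cannot be parsed."""


class LexiconValidationError(ValueError):
    """Raised when a parsed lexicon violates a schema invariant."""


@dataclass(frozen=True)
class ConceptClass:
    class_id: str
    name: str
    description: str = ""


@dataclass(frozen=True)
class AttributeDef:
    attribute_id: str
    class_id: str
    name: str
    surface_forms: tuple[str, ...]
    is_nonspecific: bool = False


@dataclass(frozen=True)
class Lexicon:
    """Validated concept schema plus corpus-query term lists."""

    classes: tuple[ConceptClass, ...]
    attributes: tuple[AttributeDef, ...]
    inclusion_terms: tuple[str, ...]
    exclusion_terms: tuple[str, ...]
    fp_terms: tuple[str, ...]

    def class_ids(self) -> list[str]:
        return [c.class_id for c in self.classes]

    def get_class(self, class_id: str) -> ConceptClass:
        for c in self.classes:
            if c.class_id == class_id:
                return c
        raise KeyError(class_id)

    def attributes_of(self, class_id: str) -> list[AttributeDef]:
        return [a for a in self.attributes if a.class_id == class_id]

    def get_attribute(self, attribute_id: str) -> AttributeDef:
        for a in self.attributes:
            if a.attribute_id == attribute_id:
                return a
        raise KeyError(attribute_id)

    def label_pairs(self) -> set[tuple[str, str]]:
        return {(a.class_id, a.attribute_id) for a in self.attributes}


def _norm_terms(terms: Iterable[str]) -> tuple[str, ...]:
    out, seen = [], set()
    for t in terms:
        n = normalize(str(t))
        if n and n not in seen:
            seen.add(n)
            out.append(n)
    return tuple(out)


def _lexicon_from_dict(doc: dict, source: str = "<dict>") -> Lexicon:
    try:
        raw_classes = doc["classes"]
    except (KeyError, TypeError):
        raise LexiconFormatError(f"{source}: missing top-level 'classes' mapping")
    classes, attributes = [], []
    for cls in raw_classes:
        classes.append(
            ConceptClass(
                class_id=str(cls["class_id"]),
                name=str(cls.get("name", cls["class_id"])),
                description=str(cls.get("description", "")),
            )
        )
        for attr in cls.get("attributes", []):
            attributes.append(
                AttributeDef(
                    attribute_id=str(attr["attribute_id"]),
                    class_id=str(cls["class_id"]),
                    name=str(attr.get("name", attr["attribute_id"])),
                    surface_forms=_norm_terms(attr.get("surface_forms", [])),
                    is_nonspecific=bool(attr.get("nonspecific", False)),
                )
            )
    lex = Lexicon(
        classes=tuple(classes),
        attributes=tuple(attributes),
        inclusion_terms=_norm_terms(doc.get("inclusion_terms", [])),
        exclusion_terms=_norm_terms(doc.get("exclusion_terms", [])),
        fp_terms=_norm_terms(doc.get("fp_terms", [])),
    )
    violations = validate_lexicon(lex)
    if violations:
        raise LexiconValidationError(f"{source}: " + "; ".join(violations))
    return lex


def load_lexicon(path, format: str = "yaml") -> Lexicon:
    """Load and validate a lexicon config.

    ``format="yaml"`` accepts the documented YAML/JSON structure
    (``classes -> attributes -> {surface_forms, nonspecific}`` plus top-level
    ``inclusion_terms`` / ``exclusion_terms`` / ``fp_terms``).
    ``format="tabular"`` accepts the flat CSV written by :func:`save_lexicon`.
    All terms are normalized on load with the same normalization applied to
    posts.
    """
    path = Path(path)
    if format == "yaml":
        try:
            doc = yaml.safe_load(path.read_text(encoding="utf-8"))
        except yaml.YAMLError as exc:
            raise LexiconFormatError(f"{path}: {exc}") from exc
        if not isinstance(doc, dict):
            raise LexiconFormatError(f"{path}: top level must be a mapping")
        return _lexicon_from_dict(doc, source=str(path))
    if format == "tabular":
        return _load_tabular(path)
    raise ValueError(f"unknown lexicon format {format!r}")


def _load_tabular(path: Path) -> Lexicon:
    doc: dict = {"classes": [], "inclusion_terms": [], "exclusion_terms": [], "fp_terms": []}
    by_class: dict[str, dict] = {}
    by_attr: dict[str, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        for lineno, row in enumerate(reader, start=2):
            kind = (row.get("record_type") or "").strip()
            if kind == "class":
                c = {
                    "class_id": row["class_id"],
                    "name": row.get("name") or row["class_id"],
                    "description": row.get("description") or "",
                    "attributes": [],
                }
                by_class[row["class_id"]] = c
                doc["classes"].append(c)
            elif kind == "surface":
                aid = row["attribute_id"]
                if aid not in by_attr:
                    attr = {
                        "attribute_id": aid,
                        "name": row.get("name") or aid,
                        "nonspecific": (row.get("nonspecific") or "").lower() in ("1", "true", "yes"),
                        "surface_forms": [],
                    }
                    by_attr[aid] = attr
                    cid = row["class_id"]
                    if cid not in by_class:
                        raise LexiconFormatError(
                            f"{path}:{lineno}: surface row references unknown class {cid!r}"
                        )
                    by_class[cid]["attributes"].append(attr)
                by_attr[aid]["surface_forms"].append(row["term"])
            elif kind in ("inclusion", "exclusion", "fp"):
                doc[f"{kind}_terms"].append(row["term"])
            else:
                raise LexiconFormatError(f"{path}:{lineno}: unknown record_type {kind!r}")
    return _lexicon_from_dict(doc, source=str(path))


def save_lexicon(lex: Lexicon, path, format: str = "yaml") -> None:
    """Serialize a lexicon so that :func:`load_lexicon` round-trips it."""
    path = Path(path)
    if format == "yaml":
        doc = {
            "classes": [
                {
                    "class_id": c.class_id,
                    "name": c.name,
                    "description": c.description,
                    "attributes": [
                        {
                            "attribute_id": a.attribute_id,
                            "name": a.name,
                            "nonspecific": a.is_nonspecific,
                            "surface_forms": list(a.surface_forms),
                        }
                        for a in lex.attributes_of(c.class_id)
                    ],
                }
                for c in lex.classes
            ],
            "inclusion_terms": list(lex.inclusion_terms),
            "exclusion_terms": list(lex.exclusion_terms),
            "fp_terms": list(lex.fp_terms),
        }
        path.write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True), encoding="utf-8")
        return
    if format == "tabular":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(
                fh,
                fieldnames=[
                    "record_type", "class_id", "attribute_id",
                    "name", "description", "nonspecific", "term",
                ],
            )
            writer.writeheader()
            for c in lex.classes:
                writer.writerow(
                    {"record_type": "class", "class_id": c.class_id,
                     "name": c.name, "description": c.description}
                )
            for a in lex.attributes:
                for term in a.surface_forms:
                    writer.writerow(
                        {"record_type": "surface", "class_id": a.class_id,
                         "attribute_id": a.attribute_id, "name": a.name,
                         "nonspecific": "true" if a.is_nonspecific else "false",
                         "term": term}
                    )
            for kind, terms in (
                ("inclusion", lex.inclusion_terms),
                ("exclusion", lex.exclusion_terms),
                ("fp", lex.fp_terms),
            ):
                for term in terms:
                    writer.writerow({"record_type": kind, "term": term})
        return
    raise ValueError(f"unknown lexicon format {format!r}")


def validate_lexicon(lex: Lexicon) -> list[str]:
    """Check every schema invariant; returns violations (empty iff valid)."""
    v: list[str] = []
    seen_cls: set[str] = set()
    for c in lex.classes:
        if c.class_id in seen_cls:
            v.append(f"class {c.class_id!r}: duplicate class_id")
        seen_cls.add(c.class_id)
        if not c.name.strip():
            v.append(f"class {c.class_id!r}: empty name")

    seen_attr: set[str] = set()
    nonspecific_per_class: dict[str, int] = {}
    for a in lex.attributes:
        if a.attribute_id in seen_attr:
            v.append(f"attribute {a.attribute_id!r}: duplicate attribute_id")
        seen_attr.add(a.attribute_id)
        if a.class_id not in seen_cls:
            v.append(f"attribute {a.attribute_id!r}: unknown class_id {a.class_id!r}")
        if not a.surface_forms:
            v.append(f"attribute {a.attribute_id!r}: no surface forms")
        for term in a.surface_forms:
            if term != term.strip() or term != term.lower() or normalize(term) != term:
                v.append(f"attribute {a.attribute_id!r}: surface form {term!r} not normalized")
        if a.is_nonspecific:
            nonspecific_per_class[a.class_id] = nonspecific_per_class.get(a.class_id, 0) + 1
    for cid, n in nonspecific_per_class.items():
        if n > 1:
            v.append(f"class {cid!r}: {n} non-specific attributes (at most one allowed)")

    overlap = set(lex.inclusion_terms) & set(lex.exclusion_terms)
    if overlap:
        v.append(f"inclusion/exclusion overlap: {sorted(overlap)}")
    for term in lex.exclusion_terms:
        if not any(inc in term for inc in lex.inclusion_terms):
            v.append(f"exclusion term {term!r} contains no inclusion term as substring")
    for term in lex.fp_terms:
        if term != term.lower():
            v.append(f"fp term {term!r} not lowercase")
    return v


def builtin_hl_lexicon() -> Lexicon:
    """The bundled Hodgkin's-lymphoma concept schema.

    Nine classes with their attributes and a non-specific fallback where one
    is defined, plus the inclusion ("hodgkin" lexical variants), exclusion
    ("non-hodgkin" variants), and namesake false-positive term lists.

    The surface-form dictionaries and the namesake list are curated
    best-effort stand-ins assembled from published guideline excerpts; they
    are intentionally extensible via a user config file
    (see :func:`load_lexicon`).
    """
    with resources.files("hlner").joinpath("data", _BUILTIN_RESOURCE).open(
        "r", encoding="utf-8"
    ) as fh:
        doc = yaml.safe_load(fh)
    return _lexicon_from_dict(doc, source=f"builtin:{_BUILTIN_RESOURCE}")
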