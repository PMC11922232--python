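"""Format readers and writers shared by the CLI stages.

Formats are deliberately plain text: JSONL for posts and gold labels, CSV
for mention tables and reports, and a simplified eHOST-style XML dialect for
span-level gold annotations (one ``<post_id>.xml`` per post holding
``<annotation>`` elements with a span, the spanned text, and the
class/attribute mention). Every writer stamps a provenance header; readers
skip it transparently.
"""

from __future__ import annotations

import csv
import hashlib
import json
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Iterable, Optional, Sequence

from . import __version__
from .evaluation import GoldAnnotation
from .matcher import Mention
from .preprocess import CleanPost, RawPost

MENTION_COLUMNS = [
    "post_id", "class_id", "attribute_id", "start", "end",
    "matched_text", "lexicon_term", "distance",
]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable config object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def provenance(seed: Optional[int] = None, config=None) -> dict:
    meta = {"tool": "hlner", "version": __version__}
    if seed is not None:
        meta["seed"] = seed
    if config is not None:
        meta["config_hash"] = config_hash(config)
    return meta


def _meta_line(seed, config) -> str:
    return json.dumps({"_meta": provenance(seed, config)}, sort_keys=True)


# ---------------------------------------------------------------- posts

def read_posts(path, format: Optional[str] = None) -> list[RawPost]:
    """Read raw posts from JSONL (``id``/``post_id``, ``text``, optional
    ``created_at``/``geo``) or headered CSV; format inferred from suffix."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    posts: list[RawPost] = []
    if fmt == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
                if "_meta" in obj:
                    continue
                pid = obj.get("post_id", obj.get("id"))
                if pid is None:
                    raise ValueError(f"{path}:{lineno}: record has no post_id/id field")
                posts.append(
                    RawPost(post_id=str(pid), text=str(obj.get("text", "")),
                            created_at=obj.get("created_at"), geo=obj.get("geo"))
                )
    elif fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(row for row in fh if not row.startswith("#"))
            for row in reader:
                pid = row.get("post_id") or row.get("id")
                if pid is None:
                    raise ValueError(f"{path}: CSV must have a post_id or id column")
                posts.append(
                    RawPost(post_id=str(pid), text=row.get("text", ""),
                            created_at=row.get("created_at") or None)
                )
    else:
        raise ValueError(f"unknown posts format {fmt!r}")
    return posts


def write_posts_jsonl(posts: Iterable[RawPost], path, seed=None, config=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_line(seed, config) + "\n")
        for p in posts:
            obj = {"post_id": p.post_id, "text": p.text}
            if p.created_at is not None:
                obj["created_at"] = p.created_at
            if p.geo is not None:
                obj["geo"] = p.geo
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


# ----------------------------------------------------------- clean posts

def write_cleanposts_jsonl(posts: Iterable[CleanPost], path, seed=None, config=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_line(seed, config) + "\n")
        for p in posts:
            obj = {
                "post_id": p.post_id,
                "text": p.text,
                "status": p.status,
                "exclusion_reason": p.exclusion_reason,
            }
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def read_cleanposts_jsonl(path) -> list[CleanPost]:
    posts: list[CleanPost] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            if "_meta" in obj:
                continue
            posts.append(
                CleanPost(
                    post_id=str(obj["post_id"]),
                    text=obj["text"],
                    status=obj.get("status", "retained"),
                    exclusion_reason=obj.get("exclusion_reason"),
                )
            )
    return posts


# -------------------------------------------------------------- mentions

def write_mentions_csv(mentions: Sequence[Mention], path, seed=None, config=None) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("# " + _meta_line(seed, config) + "\n")
        writer = csv.writer(fh)
        writer.writerow(MENTION_COLUMNS)
        for m in mentions:
            writer.writerow(
                [m.post_id, m.class_id, m.attribute_id, m.start, m.end,
                 m.matched_text, m.lexicon_term, m.distance]
            )


def read_mentions_csv(path) -> list[Mention]:
    mentions: list[Mention] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        for row in reader:
            mentions.append(
                Mention(
                    post_id=row["post_id"],
                    class_id=row["class_id"],
                    attribute_id=row["attribute_id"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    matched_text=row["matched_text"],
                    lexicon_term=row["lexicon_term"],
                    distance=int(row["distance"]),
                )
            )
    return mentions


# ------------------------------------------------------------------ gold

def write_gold_jsonl(annotations: Sequence[dict], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ann in annotations:
            fh.write(json.dumps(ann, sort_keys=True) + "\n")


def write_gold_xml(annotations: Sequence[dict], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ann in annotations:
        root = ET.Element("annotations", {"post_id": ann["post_id"]})
        for label in ann["labels"]:
            el = ET.SubElement(root, "annotation")
            ET.SubElement(el, "span", {"start": str(label["start"]), "end": str(label["end"])})
            ET.SubElement(el, "spannedText").text = label.get("text", "")
            ET.SubElement(
                el, "mention",
                {"class_id": label["class_id"], "attribute_id": label["attribute_id"]},
            )
        tree = ET.ElementTree(root)
        ET.indent(tree)
        tree.write(directory / f"{ann['post_id']}.xml", encoding="unicode",
                   xml_declaration=True)


def read_annotations(path, format: Optional[str] = None, lex=None):
    """Read gold annotations from JSONL or an eHOST-style XML directory.

    Returns ``(annotations, rejects)``: when ``lex`` is given, labels that do
    not resolve in the lexicon are reported in ``rejects`` (as
    ``(post_id, class_id, attribute_id)``), never silently dropped.
    """
    path = Path(path)
    fmt = format or ("ehost-xml" if path.is_dir() else "jsonl")
    records: list[dict] = []
    if fmt == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
                if "_meta" in obj:
                    continue
                records.append(obj)
    elif fmt == "ehost-xml":
        for xml_path in sorted(path.glob("*.xml")):
            try:
                root = ET.parse(xml_path).getroot()
            except ET.ParseError as exc:
                raise ValueError(f"{xml_path}: malformed XML: {exc}") from exc
            labels = []
            for el in root.findall("annotation"):
                span = el.find("span")
                mention = el.find("mention")
                if span is None or mention is None:
                    raise ValueError(f"{xml_path}: annotation missing span or mention")
                spanned = el.findtext("spannedText") or ""
                labels.append(
                    {
                        "class_id": mention.get("class_id"),
                        "attribute_id": mention.get("attribute_id"),
                        "start": int(span.get("start")),
                        "end": int(span.get("end")),
                        "text": spanned,
                    }
                )
            records.append({"post_id": root.get("post_id"), "labels": labels})
    else:
        raise ValueError(f"unknown gold format {fmt!r}")

    valid = lex.label_pairs() if lex is not None else None
    annotations: list[GoldAnnotation] = []
    rejects: list[tuple[str, str, str]] = []
    for rec in records:
        labels = []
        spans = []
        for label in rec.get("labels", []):
            pair = (label["class_id"], label["attribute_id"])
            if valid is not None and pair not in valid:
                rejects.append((rec["post_id"], *pair))
                continue
            labels.append(pair)
            spans.append((label["class_id"], label["attribute_id"],
                          int(label.get("start", -1)), int(label.get("end", -1))))
        annotations.append(
            GoldAnnotation(post_id=str(rec["post_id"]), labels=frozenset(labels),
                           spans=tuple(spans))
        )
    return annotations, rejects


# ---------------------------------------------------------------- tables

def write_frame_csv(frame, path, seed=None, config=None) -> None:
    """Write a pandas DataFrame with a provenance comment header."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("# " + _meta_line(seed, config) + "\n")
        frame.to_csv(fh, index=True)
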