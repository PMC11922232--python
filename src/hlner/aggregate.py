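"""Frequency reporting: per-class/attribute counts and percentages from a
mention table, with attribute-grouping rules (e.g. merging stage rows into
early/advanced groups).

Counting unit is configurable: ``posts`` (default; distinct posts with at
least one mention of the attribute) or ``mentions`` (raw mention events).
Percentages use half-up rounding to match printed report tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

__all__ = [
    "FrequencyRow",
    "FrequencyTable",
    "GroupingRule",
    "percent",
    "count_frequencies",
    "apply_grouping",
]


def percent(numerator: int, denominator: int, decimals: int = 2) -> float:
    """``100 * numerator / denominator`` rounded half-up to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(q, rounding=ROUND_HALF_UP)
    return float(value)


@dataclass(frozen=True)
class FrequencyRow:
    class_id: str
    attribute_id: str
    count: int
    percent: float  # share of the class total


@dataclass
class FrequencyTable:
    """Counts and within-class percentages per (class, attribute), plus
    class totals and their share of the corpus denominator."""

    unit: str
    denominator: int
    rows: list[FrequencyRow]
    class_totals: dict[str, int]
    class_percents: dict[str, float]
    decimals: int = 2
    # distinct-post bookkeeping, kept so groupings can form true unions
    _attr_posts: dict = field(default_factory=dict, repr=False)
    _class_posts: dict = field(default_factory=dict, repr=False)

    def to_frame(self):
        import pandas as pd

        records = []
        for row in self.rows:
            records.append(
                {
                    "class_id": row.class_id,
                    "attribute_id": row.attribute_id,
                    "count": row.count,
                    "percent": row.percent,
                    "class_total": self.class_totals.get(row.class_id, 0),
                    "class_percent": self.class_percents.get(row.class_id),
                }
            )
        return pd.DataFrame.from_records(
            records,
            columns=["class_id", "attribute_id", "count", "percent",
                     "class_total", "class_percent"],
        )


def count_frequencies(
    mentions: Sequence,
    lex,
    unit: str = "posts",
    denominator: Optional[int] = None,
    decimals: int = 2,
) -> FrequencyTable:
    """Build the frequency table from a mention table.

    With ``unit="posts"`` an attribute's count is the number of distinct
    posts containing at least one mention of it, and the class total is the
    number of distinct posts with any mention of the class; with
    ``unit="mentions"`` raw mention events are counted. ``denominator``
    (default: distinct posts in the table) scales the class-level percents.
    """
    if unit not in ("posts", "mentions"):
        raise ValueError(f"unknown counting unit {unit!r}")
    valid = lex.label_pairs()
    for m in mentions:
        if (m.class_id, m.attribute_id) not in valid:
            raise ValueError(
                f"mention references unknown label ({m.class_id!r}, {m.attribute_id!r})"
            )

    attr_posts: dict[tuple[str, str], set] = {}
    class_posts: dict[str, set] = {}
    attr_events: dict[tuple[str, str], int] = {}
    class_events: dict[str, int] = {}
    all_posts = set()
    for m in mentions:
        key = (m.class_id, m.attribute_id)
        attr_posts.setdefault(key, set()).add(m.post_id)
        class_posts.setdefault(m.class_id, set()).add(m.post_id)
        attr_events[key] = attr_events.get(key, 0) + 1
        class_events[m.class_id] = class_events.get(m.class_id, 0) + 1
        all_posts.add(m.post_id)

    if denominator is None:
        denominator = len(all_posts)

    if unit == "posts":
        attr_counts = {k: len(v) for k, v in attr_posts.items()}
        class_totals = {k: len(v) for k, v in class_posts.items()}
    else:
        attr_counts = attr_events
        class_totals = class_events

    rows: list[FrequencyRow] = []
    for cls in lex.classes:
        total = class_totals.get(cls.class_id, 0)
        for attr in lex.attributes_of(cls.class_id):
            key = (cls.class_id, attr.attribute_id)
            if key not in attr_counts:
                continue
            rows.append(
                FrequencyRow(
                    class_id=cls.class_id,
                    attribute_id=attr.attribute_id,
                    count=attr_counts[key],
                    percent=percent(attr_counts[key], total, decimals),
                )
            )
    class_percents = {
        cid: percent(total, denominator, decimals) if denominator > 0 else None
        for cid, total in class_totals.items()
    }
    return FrequencyTable(
        unit=unit,
        denominator=denominator,
        rows=rows,
        class_totals=dict(class_totals),
        class_percents=class_percents,
        decimals=decimals,
        _attr_posts=attr_posts,
        _class_posts=class_posts,
    )


@dataclass(frozen=True)
class GroupingRule:
    """Merge ``source_attributes`` of ``class_id`` into one ``target`` row."""

    class_id: str
    target: str
    source_attributes: tuple[str, ...]


def apply_grouping(table: FrequencyTable, rules: Sequence[GroupingRule]) -> FrequencyTable:
    """Replace source rows by merged target rows.

    With ``unit="posts"`` a merged count is the number of *distinct* posts
    across the sources (a post mentioning two sources counts once); with
    ``unit="mentions"`` counts are summed. Class totals and the denominator
    are unchanged.
    """
    if not rules:
        return table
    present = {(r.class_id, r.attribute_id) for r in table.rows}
    for rule in rules:
        for src in rule.source_attributes:
            if (rule.class_id, src) not in present:
                raise ValueError(
                    f"grouping rule {rule.target!r}: attribute {src!r} not in table "
                    f"for class {rule.class_id!r}"
                )
    targets = [r.target for r in rules]
    if len(set(targets)) != len(targets):
        raise ValueError("grouping rule targets must be unique")

    rows = list(table.rows)
    attr_posts = dict(table._attr_posts)
    for rule in rules:
        sources = set(rule.source_attributes)
        merged_rows = [r for r in rows if r.class_id == rule.class_id and r.attribute_id in sources]
        rows = [r for r in rows if not (r.class_id == rule.class_id and r.attribute_id in sources)]
        if table.unit == "posts":
            merged_posts = set()
            for src in sources:
                merged_posts |= attr_posts.pop((rule.class_id, src), set())
            count = len(merged_posts)
            attr_posts[(rule.class_id, rule.target)] = merged_posts
        else:
            count = sum(r.count for r in merged_rows)
        total = table.class_totals.get(rule.class_id, 0)
        insert_at = min(
            (i for i, r in enumerate(rows) if r.class_id == rule.class_id),
            default=len(rows),
        )
        rows.insert(
            insert_at,
            FrequencyRow(
                class_id=rule.class_id,
                attribute_id=rule.target,
                count=count,
                percent=percent(count, total, table.decimals),
            ),
        )
    return FrequencyTable(
        unit=table.unit,
        denominator=table.denominator,
        rows=rows,
        class_totals=dict(table.class_totals),
        class_percents=dict(table.class_percents),
        decimals=table.decimals,
        _attr_posts=attr_posts,
        _class_posts=dict(table._class_posts),
    )
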