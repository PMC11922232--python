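"""Corpus construction: text standardization, query filtering, deduplication
and namesake false-positive exclusion.

The pipeline turns raw posts into :class:`CleanPost` records in four fixed
steps: ``normalize`` -> ``query_filter`` -> ``dedupe`` -> ``fp_post_filter``.
Each excluded post keeps a machine-readable ``exclusion_reason`` so that
attrition counts can be reconstructed from the output alone.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "RawPost",
    "CleanPost",
    "EXCLUSION_REASONS",
    "normalize",
    "query_filter",
    "fp_post_filter",
    "dedupe",
    "preprocess_corpus",
]

EXCLUSION_REASONS = (
    "no_inclusion_match",
    "exclusion_only",
    "duplicate",
    "fp_hodgkin",
    "empty_after_normalization",
)

_USERNAME_RE = re.compile(r"@\w+")
_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)")
_NON_ASCII_RE = re.compile(r"[^\x00-\x7f]")
_NON_ALNUM_RE = re.compile(r"[^a-z0-9]+")


@dataclass(frozen=True)
class RawPost:
    """One unprocessed input post."""

    post_id: str
    text: str
    created_at: Optional[str] = None
    geo: Optional[dict] = None


@dataclass(frozen=True)
class CleanPost:
    """A normalized post together with its retention decision.

    ``status`` is ``"excluded"`` iff ``exclusion_reason`` is set. Geo and
    timestamp fields are carried through untouched; no geo filtering is
    applied.
    """

    post_id: str
    text: str
    status: str = "retained"
    exclusion_reason: Optional[str] = None
    created_at: Optional[str] = None
    geo: Optional[dict] = None

    def __post_init__(self) -> None:
        if (self.status == "excluded") != (self.exclusion_reason is not None):
            raise ValueError(
                f"post {self.post_id!r}: status={self.status!r} inconsistent "
                f"with exclusion_reason={self.exclusion_reason!r}"
            )
        if self.exclusion_reason is not None and self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion_reason {self.exclusion_reason!r}")


def normalize(text: str) -> str:
    """Standardize raw post text into the pipeline's canonical form.

    Applies, in order: lowercasing; removal of @-prefixed usernames; removal
    of URLs (http/https/www); removal of emoji and all other non-ASCII
    characters; replacement of remaining non-alphanumeric characters by
    spaces; whitespace collapse and strip. The output alphabet is
    ``{a-z, 0-9, space}`` and the function is idempotent.
    """
    text = text.lower()
    text = _USERNAME_RE.sub(" ", text)
    text = _URL_RE.sub(" ", text)
    text = _NON_ASCII_RE.sub(" ", text)
    text = _NON_ALNUM_RE.sub(" ", text)
    return text.strip()


def _find_spans(text: str, term: str) -> list[tuple[int, int]]:
    """All (start, end) occurrences of ``term`` in ``text`` (substring)."""
    spans = []
    i = text.find(term)
    while i != -1:
        spans.append((i, i + len(term)))
        i = text.find(term, i + 1)
    return spans


def query_filter(text: str, lex) -> str:
    """Decide ``"match"``/``"no_match"`` for a normalized post.

    A post matches iff at least one occurrence of an inclusion term is not
    contained in an occurrence of any exclusion term. Exclusion terms act by
    span-masking, so a post mentioning both the target disease and its
    "non-" counterpart still matches.
    """
    excl_spans = []
    for term in lex.exclusion_terms:
        excl_spans.extend(_find_spans(text, term))
    for term in lex.inclusion_terms:
        for start, end in _find_spans(text, term):
            masked = any(es <= start and end <= ee for es, ee in excl_spans)
            if not masked:
                return "match"
    return "no_match"


def _has_inclusion(text: str, lex) -> bool:
    return any(term in text for term in lex.inclusion_terms)


def fp_post_filter(text: str, lex) -> str:
    """Post-level namesake filter: ``"exclude_fp"`` iff any fp_term occurs.

    This replicates the upstream study design of dropping whole posts that
    contain a false-positive namesake term, even when a true disease
    reference is also present.
    """
    for term in lex.fp_terms:
        if term in text:
            return "exclude_fp"
    return "keep"


def dedupe(posts: Sequence[CleanPost]) -> list[CleanPost]:
    """Mark later posts with identical normalized text as duplicates.

    Stable: for each group of equal texts the first post in input order is
    kept; already-excluded posts are passed through and do not claim a text.
    """
    seen: set[str] = set()
    out: list[CleanPost] = []
    for post in posts:
        if post.status == "excluded":
            out.append(post)
            continue
        if post.text in seen:
            out.append(
                CleanPost(
                    post_id=post.post_id,
                    text=post.text,
                    status="excluded",
                    exclusion_reason="duplicate",
                    created_at=post.created_at,
                    geo=post.geo,
                )
            )
        else:
            seen.add(post.text)
            out.append(post)
    return out


@dataclass
class PreprocessSummary:
    """Attrition counts for one preprocessing run."""

    n_input: int = 0
    n_retained: int = 0
    by_reason: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        d = {"input": self.n_input, "retained": self.n_retained}
        for reason in EXCLUSION_REASONS:
            d[reason] = self.by_reason.get(reason, 0)
        return d


def preprocess_corpus(
    posts: Iterable[RawPost], lex
) -> tuple[list[CleanPost], PreprocessSummary]:
    """Run the full normalize -> query filter -> dedupe -> FP filter pipeline.

    Returns one :class:`CleanPost` per input post (conservation: retained +
    excluded = input) plus a :class:`PreprocessSummary` of per-reason counts.
    Raises ``ValueError`` on duplicate post ids.
    """
    posts = list(posts)
    ids = [p.post_id for p in posts]
    if len(set(ids)) != len(ids):
        dupes = [pid for pid, c in Counter(ids).items() if c > 1]
        raise ValueError(f"duplicate post_id(s): {dupes[:5]}")

    staged: list[CleanPost] = []
    for post in posts:
        text = normalize(post.text)
        if not text:
            reason = "empty_after_normalization"
        elif query_filter(text, lex) == "match":
            reason = None
        elif _has_inclusion(text, lex):
            reason = "exclusion_only"
        else:
            reason = "no_inclusion_match"
        staged.append(
            CleanPost(
                post_id=post.post_id,
                text=text,
                status="retained" if reason is None else "excluded",
                exclusion_reason=reason,
                created_at=post.created_at,
                geo=post.geo,
            )
        )

    staged = dedupe(staged)

    out: list[CleanPost] = []
    for post in staged:
        if post.status == "retained" and fp_post_filter(post.text, lex) == "exclude_fp":
            post = CleanPost(
                post_id=post.post_id,
                text=post.text,
                status="excluded",
                exclusion_reason="fp_hodgkin",
                created_at=post.created_at,
                geo=post.geo,
            )
        out.append(post)

    summary = PreprocessSummary(n_input=len(out))
    for post in out:
        if post.status == "retained":
            summary.n_retained += 1
        else:
            summary.by_reason[post.exclusion_reason] += 1
    return out, summary


def attrition(total: int, *reserved: int) -> int:
    """Posts remaining for deployment after reserving annotation subsets."""
    remaining = total - sum(reserved)
    if remaining < 0:
        raise ValueError("reserved subsets exceed corpus size")
    return remaining
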