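"""Dictionary NER over normalized posts.

Candidate token n-grams (surface and, optionally, lemma form) are compared
against every attribute surface form with an optimal-string-alignment
Damerau-Levenshtein distance (insertions, deletions, substitutions, adjacent
transpositions; each substring edited at most once). Overlapping hits within
a class are resolved longest-span-first, then lowest distance, then leftmost,
so a post can carry mentions in several classes but never overlapping
mentions within one class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional

from .preprocess import _find_spans

__all__ = [
    "Token",
    "Mention",
    "MatchConfig",
    "tokenize",
    "lemmatize",
    "dl_distance",
    "approx_match",
    "extract_mentions",
    "annotate_corpus",
]

_WORD_RE = re.compile(r"\S+")
_VOWELS = set("aeiou")
# stems ending in these letters usually dropped a final "e" ("relaps-",
# "diagnos-", "surviv-")
_E_RESTORE = set("scvzgu")


@dataclass(frozen=True)
class Token:
    text: str
    lemma: str
    pos: str
    start: int
    end: int


@dataclass(frozen=True)
class Mention:
    """One extracted (class, attribute) hit. Offsets are 0-based half-open."""

    post_id: str
    class_id: str
    attribute_id: str
    start: int
    end: int
    matched_text: str
    lexicon_term: str
    distance: int


@dataclass(frozen=True)
class MatchConfig:
    """Approximate-matching thresholds.

    ``max_distance_rule`` maps a minimum term length to the allowed edit
    distance; the rule must be non-decreasing in term length. The default
    forces exact matches for terms shorter than 5 characters, allows one
    edit for 5-9 characters and two for 10 or more.
    """

    max_distance_rule: tuple[tuple[int, int], ...] = ((0, 0), (5, 1), (10, 2))
    max_ngram: int = 4
    use_lemmas: bool = True

    def __post_init__(self) -> None:
        rule = tuple(sorted(self.max_distance_rule))
        object.__setattr__(self, "max_distance_rule", rule)
        dists = [d for _, d in rule]
        if any(b < a for a, b in zip(dists, dists[1:])):
            raise ValueError("max_distance_rule must be non-decreasing in term length")
        if not rule or rule[0][0] != 0:
            raise ValueError("max_distance_rule must cover length 0")

    def allowed_distance(self, term_length: int) -> int:
        dist = 0
        for min_len, d in self.max_distance_rule:
            if term_length >= min_len:
                dist = d
        return dist


def _is_roman(word: str) -> bool:
    return bool(word) and set(word) <= set("ivxlcdm")


def lemmatize(word: str) -> str:
    """Crude suffix-rule lemmatizer for the normalized alphabet.

    Handles regular plural/past/progressive suffixes with consonant
    un-doubling and heuristic final-"e" restoration ("relapsed" ->
    "relapse", "diagnosed" -> "diagnose"). Irregular forms pass through
    unchanged; surface matching remains the primary route.
    """
    w = word
    if len(w) < 4 or w.isdigit():
        return w
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("sses"):
        return w[:-2]
    for suffix in ("ing", "ed"):
        if w.endswith(suffix) and len(w) - len(suffix) >= 3:
            stem = w[: -len(suffix)]
            if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
                return stem[:-1]
            if stem[-1] in _E_RESTORE and stem[-1] not in _VOWELS or (
                len(stem) >= 3
                and stem[-1] not in _VOWELS
                and stem[-2] in _VOWELS
                and stem[-3] not in _VOWELS
            ):
                return stem + "e"
            return stem
    if w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    return w


def _pos_tag(word: str) -> str:
    if word.isdigit() or _is_roman(word):
        return "NUM"
    if word.endswith(("ing", "ed")) and len(word) > 4:
        return "VERB"
    return "NOUN"


def tokenize(text: str) -> list[Token]:
    """Whitespace tokenization with character offsets into ``text``."""
    tokens = []
    for m in _WORD_RE.finditer(text):
        word = m.group()
        tokens.append(
            Token(text=word, lemma=lemmatize(word), pos=_pos_tag(word),
                  start=m.start(), end=m.end())
        )
    return tokens


def dl_distance(a: str, b: str) -> int:
    """Optimal-string-alignment Damerau-Levenshtein distance.

    Minimal number of single-character insertions, deletions, substitutions
    and adjacent transpositions converting ``a`` into ``b``, with each
    substring edited at most once.
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d = min(d, prev2[j - 2] + 1)
            cur[j] = d
        prev2, prev = prev, cur
    return prev[lb]


@lru_cache(maxsize=1 << 20)
def _bounded_dl(a: str, b: str, limit: int) -> Optional[int]:
    """``dl_distance(a, b)`` if it does not exceed ``limit``, else ``None``.

    Same optimal-string-alignment recurrence as :func:`dl_distance`, with an
    early abort once every cell of a row exceeds the limit. Memoized because
    candidate n-grams repeat heavily across a corpus.
    """
    if abs(len(a) - len(b)) > limit:
        return None
    if a == b:
        return 0
    if limit == 0:
        return None
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        d = max(la, lb)
        return d if d <= limit else None
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d = min(d, prev2[j - 2] + 1)
            cur[j] = d
        if min(cur) > limit:
            return None
        prev2, prev = prev, cur
    return prev[lb] if prev[lb] <= limit else None


def approx_match(phrase: str, term: str, cfg: Optional[MatchConfig] = None):
    """Return the edit distance if ``phrase`` matches ``term``, else ``None``.

    A hit requires ``dl_distance(phrase, term)`` to be within the distance
    allowed for ``len(term)`` under ``cfg.max_distance_rule``.
    """
    cfg = cfg or MatchConfig()
    allowed = cfg.allowed_distance(len(term))
    return _bounded_dl(phrase, term, allowed)


@dataclass(frozen=True)
class _Candidate:
    class_id: str
    attribute_id: str
    start: int
    end: int
    term: str
    distance: int


def _terms_by_token_count(lex) -> dict[int, list[tuple[str, str, str]]]:
    buckets: dict[int, list[tuple[str, str, str]]] = {}
    for attr in lex.attributes:
        for term in attr.surface_forms:
            n = len(term.split())
            buckets.setdefault(n, []).append((term, attr.class_id, attr.attribute_id))
    return buckets


def extract_mentions(post, lex, cfg: Optional[MatchConfig] = None) -> list[Mention]:
    """Extract all (class, attribute) mentions from one retained post.

    Slides token n-grams of 1..``cfg.max_ngram`` tokens over the post and
    tests the surface string (and the lemma string when ``cfg.use_lemmas``)
    against every surface form with the same token count. Spans overlapping
    a false-positive namesake term never produce mentions.
    """
    if getattr(post, "status", "retained") != "retained":
        raise ValueError(f"post {post.post_id!r} is not retained")
    cfg = cfg or MatchConfig()
    text = post.text
    tokens = tokenize(text)
    if not tokens:
        return []

    fp_spans = []
    for term in lex.fp_terms:
        fp_spans.extend(_find_spans(text, term))

    buckets = _terms_by_token_count(lex)
    candidates: list[_Candidate] = []
    for n in range(1, min(cfg.max_ngram, len(tokens)) + 1):
        terms = buckets.get(n)
        if not terms:
            continue
        for i in range(len(tokens) - n + 1):
            start = tokens[i].start
            end = tokens[i + n - 1].end
            if any(fs < end and start < fe for fs, fe in fp_spans):
                continue
            surface = text[start:end]
            phrases = [surface]
            if cfg.use_lemmas:
                lemma_phrase = " ".join(t.lemma for t in tokens[i : i + n])
                if lemma_phrase != surface:
                    phrases.append(lemma_phrase)
            for term, class_id, attribute_id in terms:
                best: Optional[int] = None
                for phrase in phrases:
                    d = approx_match(phrase, term, cfg)
                    if d is not None and (best is None or d < best):
                        best = d
                if best is not None:
                    candidates.append(
                        _Candidate(class_id, attribute_id, start, end, term, best)
                    )

    # resolve overlaps independently per class: longest span, then lowest
    # distance, then leftmost; attribute_id as a final deterministic tie-break
    mentions: list[Mention] = []
    by_class: dict[str, list[_Candidate]] = {}
    for c in candidates:
        by_class.setdefault(c.class_id, []).append(c)
    for class_id in sorted(by_class):
        chosen: list[_Candidate] = []
        ordered = sorted(
            by_class[class_id],
            key=lambda c: (-(c.end - c.start), c.distance, c.start, c.attribute_id, c.term),
        )
        for cand in ordered:
            if any(cand.start < k.end and k.start < cand.end for k in chosen):
                continue
            chosen.append(cand)
        for cand in chosen:
            mentions.append(
                Mention(
                    post_id=post.post_id,
                    class_id=cand.class_id,
                    attribute_id=cand.attribute_id,
                    start=cand.start,
                    end=cand.end,
                    matched_text=text[cand.start : cand.end],
                    lexicon_term=cand.term,
                    distance=cand.distance,
                )
            )
    mentions.sort(key=lambda m: (m.start, m.end, m.class_id, m.attribute_id))
    return mentions


def annotate_corpus(posts: Iterable, lex, cfg: Optional[MatchConfig] = None) -> list[Mention]:
    """Concatenate :func:`extract_mentions` over retained posts.

    Output is deterministically ordered by (post_id, start).
    """
    cfg = cfg or MatchConfig()
    mentions: list[Mention] = []
    for post in posts:
        if getattr(post, "status", "retained") != "retained":
            continue
        mentions.extend(extract_mentions(post, lex, cfg))
    mentions.sort(key=lambda m: (m.post_id, m.start, m.end, m.class_id, m.attribute_id))
    return mentions
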