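"""Seeded synthetic post corpora with exact gold labels.

Posts are assembled from a neutral filler vocabulary, an inclusion anchor
term, and sampled attribute surface forms (optionally corrupted with a
controlled number of edit operations), so every pipeline stage can be
exercised without downloading anything. Generated text is already in the
normalized alphabet, which keeps gold character spans valid after
preprocessing. Categories mirror the corpus conditions the pipeline must
survive: exclusion traps ("non hodgkin" variants only), namesake
false-positive distractors, irrelevant posts, and exact duplicates.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Sequence

from .preprocess import normalize

__all__ = [
    "GenConfig",
    "SyntheticPost",
    "generate_corpus",
    "inject_typos",
    "write_gold",
    "gold_annotations",
    "FILLER_VOCAB",
]

# Filler words are curated to stay beyond the default edit-distance
# thresholds of every bundled surface form (verified by the test suite via
# an end-to-end exactness check).
FILLER_VOCAB = (
    "journey", "update", "friends", "grateful", "hoping", "community",
    "everyone", "sending", "love", "support", "positive", "keeping",
    "busy", "weekend", "morning", "finally", "official", "news",
    "sharing", "story", "chapter", "thankful", "onwards", "believing",
)

_ANCHORS = ("hodgkin", "hodgkins")
_EXCLUSION_SNIPPETS = (
    "non hodgkin lymphoma",
    "non hodgkin",
    "nonhodgkins lymphoma",
)

DEFAULT_TYPO_OPS = {"insert": 1.0, "delete": 1.0, "substitute": 1.0, "transpose": 1.0}
_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class GenConfig:
    """Generator knobs; ``seed`` is mandatory and governs all randomness."""

    n_posts: int
    seed: int
    class_mix: Optional[dict] = None
    attributes_per_post: tuple[int, int] = (1, 3)
    typo_rate: float = 0.0
    typo_k: int = 1
    typo_ops: Optional[dict] = None
    typo_min_len: int = 5
    fp_rate: float = 0.0
    irrelevant_rate: float = 0.0
    duplicate_rate: float = 0.0
    exclusion_rate: float = 0.0

    def __post_init__(self) -> None:
        rates = {
            "typo_rate": self.typo_rate,
            "fp_rate": self.fp_rate,
            "irrelevant_rate": self.irrelevant_rate,
            "duplicate_rate": self.duplicate_rate,
            "exclusion_rate": self.exclusion_rate,
        }
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        if self.fp_rate + self.irrelevant_rate + self.duplicate_rate + self.exclusion_rate > 1.0:
            raise ValueError("category rates must sum to at most 1")
        if self.class_mix is not None:
            total = sum(self.class_mix.values())
            if total <= 0:
                raise ValueError("class_mix weights must sum to a positive value")
        lo, hi = self.attributes_per_post
        if not 1 <= lo <= hi:
            raise ValueError("attributes_per_post must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class SyntheticPost:
    post_id: str
    text: str
    gold: tuple  # of (class_id, attribute_id, start, end)
    category: str


def inject_typos(term: str, k: int, ops: Optional[dict] = None, seed=None) -> str:
    """Apply ``k`` random character edits to ``term``.

    Edits never touch spaces and never produce text that normalization would
    change, so ``dl_distance(term, result) <= k`` and the result stays in
    the normalized alphabet. ``seed`` may be an int or a ``random.Random``.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k > len(term):
        raise ValueError(f"k={k} exceeds term length {len(term)}")
    if k == 0:
        return term
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    weights = dict(DEFAULT_TYPO_OPS)
    if ops:
        weights.update(ops)
    op_names = [o for o in ("insert", "delete", "substitute", "transpose") if weights.get(o, 0) > 0]
    op_weights = [weights[o] for o in op_names]

    from .matcher import dl_distance

    # sequential edits can interact (a transposition across a fresh deletion
    # site, say) and push the optimal-string-alignment distance above k, so
    # verify the bound and resample when it is violated
    for _attempt in range(50):
        result = term
        ok = True
        for _ in range(k):
            for _inner in range(50):
                op = rng.choices(op_names, weights=op_weights)[0]
                cand = _apply_edit(result, op, rng)
                if cand is not None and cand and normalize(cand) == cand:
                    result = cand
                    break
            else:
                ok = False
                break
        if ok and dl_distance(term, result) <= k:
            return result
    # fallback: k substitutions at k distinct letter positions never interact
    letter_idx = [i for i, ch in enumerate(term) if ch != " "]
    chosen = rng.sample(letter_idx, min(k, len(letter_idx)))
    out = list(term)
    for idx in chosen:
        out[idx] = rng.choice([c for c in _LETTERS if c != term[idx]])
    return "".join(out)


def _apply_edit(s: str, op: str, rng: random.Random) -> Optional[str]:
    letter_idx = [i for i, ch in enumerate(s) if ch != " "]
    if op == "insert":
        pos = rng.randrange(len(s) + 1)
        return s[:pos] + rng.choice(_LETTERS) + s[pos:]
    if op == "delete":
        if not letter_idx:
            return None
        pos = rng.choice(letter_idx)
        return s[:pos] + s[pos + 1 :]
    if op == "substitute":
        if not letter_idx:
            return None
        pos = rng.choice(letter_idx)
        repl = rng.choice([c for c in _LETTERS if c != s[pos]])
        return s[:pos] + repl + s[pos + 1 :]
    if op == "transpose":
        pairs = [i for i in letter_idx if i + 1 < len(s) and s[i + 1] != " " and s[i] != s[i + 1]]
        if not pairs:
            return None
        pos = rng.choice(pairs)
        return s[:pos] + s[pos + 1] + s[pos] + s[pos + 2 :]
    raise ValueError(f"unknown edit op {op!r}")


class _PostBuilder:
    """Accumulates space-joined pieces while tracking character offsets."""

    def __init__(self) -> None:
        self.pieces: list[str] = []
        self.length = 0

    def add(self, piece: str) -> tuple[int, int]:
        start = self.length + (1 if self.pieces else 0)
        self.pieces.append(piece)
        self.length = start + len(piece)
        return start, self.length

    def text(self) -> str:
        return " ".join(self.pieces)


def _fillers(rng: random.Random, lo: int, hi: int) -> list[str]:
    return [rng.choice(FILLER_VOCAB) for _ in range(rng.randint(lo, hi))]


def generate_corpus(lex, cfg: GenConfig) -> list[SyntheticPost]:
    """Generate a reproducible corpus of :class:`SyntheticPost` records."""
    if not lex.attributes:
        raise ValueError("lexicon has no attributes to sample from")
    rng = random.Random(cfg.seed)
    class_ids = lex.class_ids()
    if cfg.class_mix is not None:
        unknown = set(cfg.class_mix) - set(class_ids)
        if unknown:
            raise ValueError(f"class_mix references unknown classes: {sorted(unknown)}")
        mix_classes = [c for c in class_ids if cfg.class_mix.get(c, 0) > 0]
        mix_weights = [cfg.class_mix[c] for c in mix_classes]
    else:
        mix_classes = class_ids
        mix_weights = [1.0] * len(class_ids)

    posts: list[SyntheticPost] = []
    relevant_pool: list[SyntheticPost] = []
    seen_texts: set[str] = set()

    for i in range(cfg.n_posts):
        post_id = f"syn{i:06d}"
        u = rng.random()
        c1 = cfg.duplicate_rate
        c2 = c1 + cfg.fp_rate
        c3 = c2 + cfg.exclusion_rate
        c4 = c3 + cfg.irrelevant_rate
        if u < c1:
            # exact repetition of an earlier relevant post (falls back to a
            # fresh relevant post while the pool is still empty)
            if relevant_pool:
                source = rng.choice(relevant_pool)
                posts.append(
                    SyntheticPost(post_id=post_id, text=source.text,
                                  gold=source.gold, category="duplicate")
                )
                continue
            post = _build_relevant(post_id, rng, lex, cfg, mix_classes, mix_weights)
        elif u < c2:
            post = _build_simple(post_id, rng, rng.choice(lex.fp_terms), "fp_distractor")
        elif u < c3:
            post = _build_simple(post_id, rng, rng.choice(_EXCLUSION_SNIPPETS), "exclusion_trap")
        elif u < c4:
            post = _build_simple(post_id, rng, None, "irrelevant")
        else:
            post = _build_relevant(post_id, rng, lex, cfg, mix_classes, mix_weights)

        post = _ensure_unique(post, seen_texts, rng)
        seen_texts.add(post.text)
        posts.append(post)
        if post.category == "relevant":
            relevant_pool.append(post)
    return posts


def _ensure_unique(post: SyntheticPost, seen: set, rng: random.Random) -> SyntheticPost:
    text = post.text
    bump = 0
    while text in seen:
        bump += 1
        text = f"{post.text} {rng.choice(FILLER_VOCAB)} {bump}{rng.randrange(10)}"
    if text is post.text or text == post.text:
        return post
    return SyntheticPost(post_id=post.post_id, text=text, gold=post.gold, category=post.category)


def _build_simple(post_id: str, rng: random.Random, snippet: Optional[str], category: str) -> SyntheticPost:
    builder = _PostBuilder()
    for w in _fillers(rng, 2, 4):
        builder.add(w)
    if snippet is not None:
        builder.add(snippet)
    for w in _fillers(rng, 1, 3):
        builder.add(w)
    return SyntheticPost(post_id=post_id, text=builder.text(), gold=(), category=category)


def _build_relevant(
    post_id: str,
    rng: random.Random,
    lex,
    cfg: GenConfig,
    mix_classes: Sequence[str],
    mix_weights: Sequence[float],
) -> SyntheticPost:
    lo, hi = cfg.attributes_per_post
    n_attrs = rng.randint(lo, hi)
    chosen: list = []
    chosen_keys: set = set()
    for _ in range(n_attrs):
        for _attempt in range(20):
            class_id = rng.choices(list(mix_classes), weights=list(mix_weights))[0]
            attr = rng.choice(lex.attributes_of(class_id))
            if (class_id, attr.attribute_id) not in chosen_keys:
                chosen_keys.add((class_id, attr.attribute_id))
                chosen.append(attr)
                break

    builder = _PostBuilder()
    for w in _fillers(rng, 2, 3):
        builder.add(w)
    builder.add(rng.choice(_ANCHORS))
    gold = []
    for attr in chosen:
        for w in _fillers(rng, 1, 2):
            builder.add(w)
        term = rng.choice(attr.surface_forms)
        surface = term
        if (
            cfg.typo_rate > 0
            and len(term) >= cfg.typo_min_len
            and rng.random() < cfg.typo_rate
        ):
            surface = inject_typos(term, cfg.typo_k, cfg.typo_ops, seed=rng)
        start, end = builder.add(surface)
        gold.append((attr.class_id, attr.attribute_id, start, end))
    for w in _fillers(rng, 1, 2):
        builder.add(w)
    return SyntheticPost(
        post_id=post_id, text=builder.text(), gold=tuple(gold), category="relevant"
    )


def gold_annotations(posts: Sequence[SyntheticPost]):
    """Convert synthetic posts into the evaluation module's gold records."""
    from .evaluation import GoldAnnotation

    out = []
    for p in posts:
        labels = frozenset((c, a) for c, a, _s, _e in p.gold)
        spans = tuple((c, a, s, e) for c, a, s, e in p.gold)
        out.append(GoldAnnotation(post_id=p.post_id, labels=labels, spans=spans))
    return out


def write_gold(posts: Sequence[SyntheticPost], format: str, path) -> None:
    """Serialize gold labels as JSONL or the simplified eHOST-style XML
    dialect (one file per post under a directory); both round-trip through
    :func:`hlner.io.read_annotations`."""
    from . import io as hio

    annotations = []
    for p in posts:
        annotations.append(
            {
                "post_id": p.post_id,
                "labels": [
                    {
                        "class_id": c,
                        "attribute_id": a,
                        "start": s,
                        "end": e,
                        "text": p.text[s:e],
                    }
                    for c, a, s, e in p.gold
                ],
            }
        )
    if format == "jsonl":
        hio.write_gold_jsonl(annotations, path)
    elif format == "ehost-xml":
        hio.write_gold_xml(annotations, path)
    else:
        raise ValueError(f"unknown gold format {format!r}")
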