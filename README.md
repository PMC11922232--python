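# hlner

Lexicon-driven named-entity-recognition pipeline for characterizing
Hodgkin's-lymphoma disease and treatment concepts in short social-media
posts. The package bundles the complete workflow as composable modules and a
CLI:

- **`hlner.lexicon`** — the concept schema: nine classes, their attributes
  (with non-specific fallbacks), surface-form dictionaries, and the
  inclusion ("hodgkin" variants) / exclusion ("non-hodgkin" variants) /
  namesake false-positive term lists. A bundled Hodgkin's-lymphoma schema is
  available via `builtin_hl_lexicon()`; custom schemas load from YAML/JSON
  or a flat CSV (`load_lexicon`). The bundled surface-form and namesake
  lists are curated best-effort stand-ins (the original supplementary word
  lists are not publicly distributable) and are meant to be extended via
  config.
- **`hlner.preprocess`** — corpus construction: text standardization
  (lowercase; strip usernames, URLs, emoji/non-ASCII; punctuation to
  spaces), inclusion/exclusion query filtering with span-masking,
  normalized-text deduplication, and post-level namesake exclusion.
- **`hlner.matcher`** — dictionary NER: whitespace tokenization with a
  rule-based lemmatizer/POS tagger, optimal-string-alignment
  Damerau-Levenshtein distance, and n-gram approximate matching with
  length-dependent thresholds (exact under 5 characters, one edit for 5-9,
  two for 10+, configurable). Offsets are 0-based half-open throughout.
- **`hlner.evaluation`** — post x class confusion counts, the nine-metric
  suite (sensitivity, specificity, precision, NPV, FPR, FDR, FNR, accuracy,
  F1; undefined ratios reported as NA, never 0), Cohen's kappa, and seeded
  gold-set splitting. The Overall column micro-averages pooled counts; a
  macro average is also emitted.
- **`hlner.aggregate`** — frequency tables (counts and half-up-rounded
  percentages per class/attribute) with configurable counting unit
  (distinct posts vs mention events) and attribute-grouping rules (e.g.
  merging stage rows into early/advanced groups as distinct-post unions).
- **`hlner.synthetic`** — seeded synthetic corpora with exact gold labels:
  relevant posts built from filler templates plus sampled surface forms
  (optionally corrupted by a bounded number of edit operations),
  "non hodgkin" exclusion traps, namesake distractors, irrelevant posts,
  and exact duplicates. Generated text is already normalized, so gold spans
  stay valid through preprocessing.
- **`hlner.cli` / `hlner.io`** — the `hlner` command with subcommands
  `simulate`, `preprocess`, `extract`, `evaluate`, `report`, and `pipeline`,
  over plain-text formats (JSONL posts/gold, CSV mentions/reports, a
  simplified eHOST-style XML gold dialect). Outputs carry provenance
  headers (tool version, config hash, seed); reruns are byte-identical.

## CLI quick start

```bash
# generate a seeded synthetic corpus with gold labels
hlner simulate --n-posts 500 --seed 7 --out-posts posts.jsonl --out-gold gold.jsonl

# clean + filter, extract mentions, score, and report frequencies
hlner preprocess --in posts.jsonl --out clean.jsonl --summary summary.csv
hlner extract --in clean.jsonl --out mentions.csv
hlner evaluate --gold gold.jsonl --pred mentions.csv --out evaluation.csv
hlner report --mentions mentions.csv --out report.csv

# or everything from one YAML run config
hlner pipeline --config run.yaml --stages simulate,preprocess,extract,evaluate,report
```

A run config is a single YAML file with per-stage blocks:

```yaml
seed: 17
workdir: out/
gen: {n_posts: 1000, typo_rate: 0.2, fp_rate: 0.05}
match: {max_ngram: 4, use_lemmas: true}
```

## Notes

- The counting unit for frequency tables defaults to distinct posts;
  mention-event counting is available via `unit="mentions"` because
  published frequency tables do not always disambiguate the two.
- The namesake false-positive filter is post-level by design: a post
  containing both a namesake term and a true disease reference is dropped.
- Dependency parsing is not part of matching; tokens carry POS/lemma only.
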