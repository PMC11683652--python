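# phrasecast

Trace how a novel phrase diffuses through a threaded online community.

Given a forum archive as chronologically ordered post records (no
timestamps — the global post ordinal is the only temporal information),
phrasecast detects mentions of a target phrase and its variants, merges
manual semantic annotations, classifies highly active "superusers",
reconstructs each adopter's participation timeline, infers how every
adopter was plausibly exposed to the phrase (direct co-presence in a
phrase-bearing thread, co-presence in an unrelated thread, or presumed
lurking), and assembles a rooted diffusion tree with mechanism labels
(social vs. self-promotion exposure) and depth/breadth statistics.

A synthetic forum generator plants a known cascade — heavy-tailed user
activity, one phrase originator, per-thread self-promotion,
exposure-conditional adoption, Bernoulli lurking — and keeps the full event
log, so the inference can be scored for exact recovery against ground
truth.

## Package layout

| module | role |
| --- | --- |
| `phrasecast.forum` | post/thread/forum model, CSV/JSONL readers, validation |
| `phrasecast.phrases` | phrase patterns, candidate detection, context rule, annotations, local-corpus novelty counts |
| `phrasecast.cohort` | participant profiles, superuser rules, cohort summaries |
| `phrasecast.diffusion` | adoption events, exposure-route classification, diffusion tree, mechanism summary |
| `phrasecast.synthetic` | seeded forum generator with planted ground truth, recovery metrics |
| `phrasecast.report` / `phrasecast.cli` | pipeline orchestration, artifact writing, graph export, CLI |
| `phrasecast.fixtures` | packaged participant table and the narrative mini-forum |

## CLI

```bash
phrasecast validate --posts posts.csv
phrasecast mentions --posts posts.csv --pattern pattern.yaml \
    --annotations annotations.csv --out mentions.csv
phrasecast cohort   --profiles profiles.csv --superuser-rule min_posts:100
phrasecast report   --posts posts.csv --profiles profiles.csv \
    --pattern pattern.yaml --annotations annotations.csv --out artifacts/
phrasecast simulate --seed 7 --out sim/ --users 200 --threads 500 \
    --adoption-prob 0.3 --lurk-prob 0.1
phrasecast fixtures --out fixture/
```

`report` writes mentions/adoptions/exposures/edge CSVs, DOT and GraphML
tree exports, a JSON summary, and a Markdown report; identical inputs
produce byte-identical artifacts. `simulate` emits the canonical posts CSV,
profiles, and a ground-truth JSON, fully determined by `--seed`.

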