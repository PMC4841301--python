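# switchminer

Rule-based mining of multiple-sclerosis (MS) treatment-switch reports from
social-media text.

## The problem

Patients with MS discuss their disease-modifying therapies (DMTs) openly on
Twitter, Facebook, forums and blogs — including why they stopped one drug
and started another. Those switch reports are hard to get from claims
databases, which record *that* a switch happened but rarely *why*.
`switchminer` implements a complete "social intelligence" analysis pipeline
for this setting, aimed at outcomes researchers and pharmacoepidemiologists:

1. **Drug lexicon & mention matching** — ten US-market DMTs of 2013–2014 in
   three route-of-administration classes (oral: Tecfidera, Gilenya, Aubagio;
   injectable BRACE: Betaseron, Rebif, Avonex, Copaxone, Extavia; IV:
   Tysabri, Novantrone), with curated misspelling aliases and optional
   Levenshtein fuzzy matching (edit distance ≤ *k*) on word tokens.
2. **Switch detection** — an ordered keyword-pattern grammar
   ("switched from *A* to *B*", "moving from *A* to *B*", "stopping *A*,
   starting *B*", and ~9 paraphrase rules) binds a FROM and a TO drug slot;
   direction comes from the rule, never from mention order. Each event gets
   a reason from a nine-category cue taxonomy (side effects, lack of
   efficacy, physician's advice, ease of use, quality-of-life worsening,
   safety concerns, insurance, cost, other) evaluated in fixed precedence
   order, plus conversation category, theme and sentiment labels.
3. **Profile extraction** — per-author age, sex, time since diagnosis and
   country from self-declared text and account fields; a US-inclusion
   filter for the switchover stream; conservative screen-name author dedup.
4. **Stratified sampling** — relevant posts stratified by platform × month;
   per-stratum sample sizes from Cochran's formula with finite-population
   correction, `n = ⌈n₀ / (1 + (n₀−1)/N)⌉` with `n₀ = z²p(1−p)/e²`
   (95% confidence, 5% margin, p = 0.5 ⇒ n₀ ≈ 384.16, n → 385 as N → ∞),
   plus 3-random-month validation sets per platform.
5. **Aggregation** — 3×3 switch matrices over (source class, destination
   class), reason frequency tables, two-column demographics summaries, and
   a representativeness comparison against embedded community-survey and
   claims-database reference populations.

Because the raw listening data behind this kind of study is never
deposited, the package ships a **synthetic corpus generator** whose
defaults encode the published study conditions (platform volumes,
demographic marginals, switch class-pair shares, reason shares) and which
emits ground-truth annotations, so every stage — and the pipeline end to
end — is testable offline.

## Worked example

```python
from switchminer import (
    CorpusConfig, generate_corpus, run_pipeline, load_lexicon, match_mentions,
)

lex = load_lexicon()
print(match_mentions("stopping Tysabri, starting gilenia", lex, max_edit=1))
# [DrugMention(post_id='', brand='Tysabri', start=9, end=16, surface='Tysabri', fuzzy=False),
#  DrugMention(post_id='', brand='Gilenya', start=27, end=34, surface='gilenia', fuzzy=True)]

config = CorpusConfig(seed=11)          # defaults = the study conditions
posts, truth = generate_corpus(config)  # 25,073 posts across 4 platforms
bundle = run_pipeline(posts, seed=11, max_edit=1)
print(bundle.funnel)
```

prints the analysis funnel (one run with seed 11):

```
{'extracted': 25073, 'relevant': 22361, 'sampled': 9511, 'authors': 4146,
 'authors_us': 3055, 'authors_excluded_no_location': 706,
 'authors_excluded_non_us': 385, 'switch_data_points_us': 1093,
 'switch_data_points_sampled_us': 476, 'reason_classified_us': 789,
 'switching_patients_us': 918}
```

i.e. of 25,073 generated posts, 22,361 pass the relevance filter (≥ 1 drug
mention, not spam, not an author duplicate), 9,511 fall in the stratified
sample, and US-located authors contribute 1,093 switch data points, 789 of
them with a classified reason.  `bundle.matrices["relevant_us"].share_of_total()`
then shows the injectable→oral cell dominating (≈ 56% of all switches),
matching the configured class-pair law.

The same run from a shell:

```bash
switchminer pipeline --seed 11 --out out/       # corpus + truth + report bundle
switchminer generate --seed 1 --out corpus/     # corpus only
switchminer detect --corpus corpus/corpus.jsonl --max-edit 1 --out ann/
switchminer sample --corpus corpus/corpus.jsonl --seed 1 --out plan/
switchminer report --corpus corpus/corpus.jsonl --seed 1 --out report/
```

## Layout

- `src/switchminer/lexicon.py` — drug lexicon, mention matching
- `src/switchminer/synth.py` — synthetic corpus generator + ground truth
- `src/switchminer/detect.py` — relevance, switch grammar, reason/label cues
- `src/switchminer/profiles.py` — demographics extraction, US filter, dedup
- `src/switchminer/sampling.py` — stratification, Cochran sizing, draws
- `src/switchminer/aggregate.py`, `pipeline.py` — tables, end-to-end runs
- `src/switchminer/published.py`, `fixtures.py` — embedded reference counts
  and count-faithful fixture builders
- `docs/methods.md` — models, parameters, design choices, limitations
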