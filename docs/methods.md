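# Methods

This note documents the models and procedures implemented in
`switchminer`, the parameters that matter, what the synthetic corpus does
and does not emulate, and the design choices made where the design was
genuinely open.

## Mention matching

Matching runs in two passes over each post.

**Exact pass.** All lexicon surfaces — brand names, unambiguous generic
names, and curated alias/misspelling forms — are compiled into a single
case-insensitive alternation, longest surface first, anchored on word
boundaries that treat hyphens and apostrophes as word-internal (so
surfaces never match inside URLs, handles or possessives). Generic names
normalize to their brand. Two interferon generics are each shared by two
brands ("interferon beta-1a": Rebif and Avonex; "interferon beta-1b":
Betaseron and Extavia); an ambiguous generic cannot identify a drug, so
those surfaces are excluded from matching with a logged warning. Alias
matches carry `fuzzy=True`, marking a non-canonical spelling.

**Fuzzy pass** (enabled when `max_edit > 0`). Word tokens not covered by
an exact match are compared to all single-token brand and alias surfaces
by Levenshtein distance (via `edlib`). A token matches only when it is at
least 5 characters long, is not a common English word (a small shipped
stoplist), is not itself a lexicon surface, and a **unique** brand attains
the minimum distance within `max_edit`. Ties across brands are discarded
rather than guessed. The default `max_edit` is 1: single-edit typos are
the dominant misspelling class for brand names, and distance 2 would bring
brands within reach of ordinary words.

The alias list shipped with the default lexicon is a curated stand-in
(two common misspellings per brand); the lexicon CSV is user-replaceable,
and validation rejects duplicate brands, cross-brand alias collisions and
unknown class labels.

## Switch grammar

Switch detection applies an ordered rule set to a normalized token stream
in which the *i*-th drug mention is replaced by the token `drugslot<i>`.
Each rule is a regular expression with FROM and TO slot placeholders and
explicitly bounded filler gaps (at most a few tokens, so a FROM and TO
slot can never be bound across more than ~15 tokens). Twelve rules ship:
the three core families — *switched from A to B*, *moving from A to B*,
*stopping A starting B* — plus nine paraphrase rules (*went from A to B*,
*switched to B from A*, *replaced A with B*, *dropped/quit/traded/gave up
A for B*, *changed/transitioned from A to B*). Direction always comes
from the rule's slot bindings, never from mention order; the *switched to
B from A* rule is the regression test for that property.

Conflicts are resolved deterministically: rules run in file order
(priority), each rule scans left to right, an event links two *distinct*
brands, and at most one event per ordered drug pair is kept per post.
Chains ("A to B … then B to C") therefore yield two events, matching the
analysis unit — switch *data points*, not patients. The grammar file is
editable JSON; extending coverage is a data change, not a code change.

## Reason, category, theme, sentiment

The reason of an event is classified from cue phrases in a clause window
— the sentence containing the TO-slot mention. Cues for the nine reason
categories are evaluated in a fixed precedence order, the categories'
descending published frequency (side effects first, "other" last), so
co-occurring cues resolve deterministically to the more common category;
no cue yields UNSPECIFIED, which is reported separately and never enters
the reason denominator. Conversation category is INFO_SEEKING when a
question mark or interrogative opener is present; theme comes from the
first of the cost/efficacy/side-effects/adherence keyword maps with a
hit; sentiment is the sign of a positive-minus-negative cue count. The
sentiment and theme lexicons are small shipped cue lists — deliberately
simple, editable, and not claimed to approximate any particular published
sentiment method.

Relevance is defined operationally (the source methodology never defines
it): a post is relevant iff it has ≥ 1 drug mention, is not spam (cue
phrases, or a bare hyperlink), and is not a byte-identical repeat of an
earlier post by the same author within 7 days. The duplicate rule is the
single documented cross-post dependency; annotation is otherwise per-post.
Manual review is modeled as an overrides file that replaces labels
field-wise and flags provenance MANUAL.

## Profile extraction and inclusion

Age ("I'm 39", "39 yo", "age 39"), diagnosis duration ("diagnosed 8
months/10 years ago", "dx in 2004" → post year − 2004), sex (declared
fields or gendered self-reference cues; contradictory cues in one post
resolve to unknown) and country (declared location or "I live in …",
through a US-state + country gazetteer; unrecognized strings stay
unknown) are extracted per post and resolved per author by the most
recent declaration. A duration exceeding the age is structurally
impossible and is dropped. The switchover stream keeps only authors
resolved to the US; authors with no location are excluded with cause
NO_LOCATION, non-US with NON_US, and the full population still feeds the
demographics tables. Cross-platform identity is exact normalized
screen-name equality only — deliberately conservative, since fuzzier
linkage would fabricate identities.

Report bins follow the published tables: ages <20, 20–29 … 60–69, with
the top bin labelled ">70" implemented as ≥ 70 (the printed bins leave
exactly-70 unassigned; this is the logged deviation). Durations use
half-open upper edges with 1–3 years = [1, 4) and 4–8 years = [4, 9),
resolving the printed gap at year 3–4 in favor of the lower label.

## Sampling

Strata are (platform, UTC calendar month). Per-stratum sizes use
Cochran's proportion formula with finite-population correction at
confidence 0.95, margin 0.05, p = 0.5 (maximum variance), ceiling to an
integer and capping at N — the standard reading of "a 95% confidence
interval with a 5% margin of error"; all three parameters are exposed.
Draws are simple random samples without replacement seeded by
`sha256(master_seed | platform | month) mod 2³¹`, so any stratum's draw
is reproducible in isolation. Validation sets pick 3 months per platform
(uniformly, from a "validation"-labelled substream) and redraw fresh
samples; overlap with the primary sample is permitted and documented. A
per-platform-aggregate mode exists behind a flag because the source
totals cannot settle whether sampling was per stratum or per platform.

## Aggregation

Percentages are computed at full precision and rounded half-up to two
decimals at presentation only; every percentage carries its denominator
and scope. Three denominators from the published study — 1684 switch data
points, 1234 reason-classified switches, 991 switching patients — are
never pooled. The pipeline reports every switch table in two labelled
scopes, `relevant_us` and `sampled_us`, because it is ambiguous whether
published switch percentages were computed on the full relevant set or
the reviewed sample. The published switch-matrix claims are themselves
mutually inconsistent by 5 events (the from-oral count 160/1684 cannot
coexist with the from-injectable 1114, from-IV 265 and total 1684);
fixture-based reproduction therefore builds each claim from its own
numerator and denominator rather than forcing one global matrix. The
representativeness comparison reports absolute percentage-point gaps
against the embedded community-survey columns and performs no hypothesis
test, since the comparison is descriptive.

## Synthetic corpus

The generator emulates the statistical structure the analysis assumes:

- **Volumes.** 9,500 / 7,580 / 7,126 / 867 posts for Twitter / Facebook /
  forums / blogs — chosen so the expected relevant counts at the default
  relevance rate (22887/25073 ≈ 0.913) equal the published per-platform
  relevant volumes, and the total equals the published 25,073 extracted.
  Per-platform irrelevance rates are assumed equal, as nothing published
  distinguishes them.
- **Switches.** A relevant post is a switch post with probability
  1684/22887 ≈ 0.074. Class pairs follow a 3×3 weight table built from
  the mutually consistent subset of the published counts (injectable→oral
  927, IV→oral 259, IV→injectable 6, from-injectable 1114, to-oral 1326,
  total 1684; the residual 305 from-oral events split 140/80/85 to
  respect the to-oral total and the described near-tie between injectable
  and IV destinations). Drugs are uniform within class, never self-pairs.
  Reasons follow the published nine-category counts plus an UNSPECIFIED
  mass of 450 = 1684 − 1234.
- **Text.** Switch posts instantiate three detectable template families
  mirroring the grammar's core patterns, plus a "hard" paraphrase family
  (default 10% of switch posts) deliberately outside the shipped
  grammar's coverage, so precision/recall tests can separate pattern
  coverage from noise. Misspellings (default rate 0.05; 0 or 0.1 in the
  test conditions) render a mention as a lexicon alias or as a
  deterministic out-of-lexicon single-edit variant pre-verified to
  fuzzy-resolve uniquely to its brand. Non-switch drug chatter, off-topic
  posts and a 2% spam fraction complete the mix, each template carrying
  hand-traced ground-truth labels.
- **Authors.** Post counts per author are 1 + Poisson(4.85) (mean ≈ 5.85,
  the published posts-per-patient ratio); 5% of authors are active on a
  second platform under the same screen name. Demographics follow the
  published marginals for sex, age bins and duration bins; durations are
  quantized to what the text declares (whole months below a year, whole
  years above) so extraction can be exact; a rejection step keeps
  duration < age. The country mix is not published; the default is 75% US,
  10% non-US, 15% undeclared — enough excluded mass to exercise both
  exclusion causes without starving the US stream. Each post declares the
  author's profile (text sentences + a declared location field) with
  probability 0.6.
- **Determinism.** One `numpy` PCG64 stream keyed by the seed drives every
  choice in a fixed order; the ground truth mirrors the detector's
  author-duplicate rule so that a rare template collision is labelled the
  way a correct system must label it.

What the generator does **not** emulate: free linguistic variation
(negation, sarcasm, slang), drug discussion outside the template bank,
author-level topic correlation, bursty posting dynamics, or any joint
structure between demographics and switching behavior. Passing closed-loop
tests therefore demonstrates correctness of the pipeline mechanics under
the stated noise model — not field performance on real social-media text,
where pattern coverage and profile declaration rates are the binding
constraints.

## Numerical and testing choices

Percent rounding is decimal half-up (not banker's). Sample-size
monotonicity and the mention-matcher's equivalence to a brute-force
position/token scan with a hand-written Levenshtein are property-tested;
the Cochran implementation is compared against an independent direct
evaluation for every N in 1…10,000. Closed-loop tests use corpora of
2,000 posts (4 × 500) and scale tests 20,000 posts (4 × 5,000), sizes at
which the smallest configured shares still have > 5 expected events and
the suite stays fast. Statistical recovery tests use 3-standard-error
binomial bands around configured shares. Report bundles are byte-stable:
sorted tables, fixed float formatting, no wall-clock content in the
manifest.

## Known limitations

- The grammar cannot bind events expressed across sentences or through
  anaphora ("I quit Rebif. The new pill is better.").
- Reason classification reads a single clause window; a reason stated in
  a different sentence is UNSPECIFIED.
- The gazetteer resolves US states and ~45 country names only; city-only
  declarations ("Springfield") stay unknown by design.
- Screen-name-only identity can both merge distinct users (same handle on
  two platforms) and split one user (different handles); the published
  methodology shares this limitation and the rule here is at least
  explicit.
- Embedded reference tables are summary constants; no patient-level
  external data is included.
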