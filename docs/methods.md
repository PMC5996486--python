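# Methods

## Problem setting

Social-media disease surveillance assumes that mentions of illness in
public short messages track the health state of the population. This
package implements the full measurement chain needed to test that
assumption — terminology-driven mention detection, location-stratified
counting, and language-pattern mining — together with a synthetic corpus
generator that encodes the two failure modes the chain is designed to
expose: frequency inflation by duplicated news titles, and the
concentration of personally relevant signal in rare terms.

## Lexicon construction

A terminology is a forest of nodes (`node_id, name, synonyms, children` in
a flat CSV). Harvesting collects the name and synonyms of every node
reachable from a chosen root, each node exactly once (depth-first
preorder; cycles are a format error, diamonds are visited once). Surface
forms then pass the *content-word filter*: a form with more than
`max_content_words` (default 3) tokens is dropped, not counting the six
function words "of", "from", "the", "a", "and", "to". Both the word list
and the bound are configurable.

Two points the filter leaves open were resolved as follows:

- **Counting unit.** Tokens are whitespace-delimited; hyphenated compounds
  count as one token. Clinical hyphenation is inconsistent enough that
  splitting would make the bound depend on orthography rather than length.
- **Dropped names with surviving synonyms.** A record whose *canonical
  name* fails the filter is dropped entirely, synonyms included — a
  synonym cannot be normalized to a name that is itself excluded from the
  dictionary. An over-long synonym of a retained name is dropped
  individually.

Normalization for lookup is lowercase + whitespace collapse; short
messages are case-chaotic, and no meaning attaches to casing in disease
names. A synonym claimed by two canonical terms keeps its first mapping
(traversal order) with a logged warning; polysemous layman forms are a
property of the terminology, and the dictionary layer does not attempt
disambiguation.

## Noise filtering

Two regular-expression families remove structured noise before analysis:
job advertisements (`#hiring`, `#job`, "job opening", "we're hiring") and
templated check-ins ("I'm at X in Y"). The families partition the corpus
(kept / job / check-in), with job precedence on double matches for stable
reporting. The shipped patterns are defaults that reproduce the canonical
examples of both families; real deployments are expected to override them
in the YAML config, and the filter is idempotent by construction.

## Geofencing

Membership is radial: airport collection within 3 km of a large airport,
hospital collection within 0.2 km of a hospital, background ("geolocated")
otherwise. Design choices:

- **Sphere, R = 6371 km, haversine.** At fence scales of 0.2–3 km the
  ellipsoidal correction is sub-metre; the haversine form is
  well-conditioned at small separations where the law of cosines is not
  (the law-of-cosines formula is therefore used as the independent test
  oracle, at separations above ~1 m).
- **Inclusive boundary** (distance ≤ radius), which makes membership
  monotone in the radius — a clean invariant to test against.
- **Flags, not labels.** A message can be inside both fences; summaries
  carry the overlap explicitly and the identity
  `n_unique = n_airport + n_hospital − n_overlap + n_geolocated` is
  asserted at construction time.
- **Brute force is the reference.** The vectorized corpus path and the
  optional latitude-band index must return distances identical to the
  scalar path; the band index stops early using the latitude separation
  alone as a lower bound on great-circle distance, which is exact at every
  latitude and needs no longitude bookkeeping.

## Mention matching

A mention is a case-insensitive occurrence of a lexicon surface form as a
whole token sequence: word boundaries on both ends (word characters are
letters and digits; underscore is a boundary), and the tokens of a
multi-word term may be separated by any run of non-word characters, so
"kidney-stone" matches "kidney stone" but "kidneystone" does not, and
hashtag bodies are searchable. Candidates are gathered canonical-first
then synonyms, and overlaps resolved longest-first, then leftmost, so no
character position contributes to two mentions. Frequencies downstream are
per-tweet: a term repeated in one message counts once, and a message with
several distinct terms counts once toward each.

## Normalization and POS patterns

Five substitutions are applied in order before tagging: (1) the tweet's
first (leftmost) mention → `DISEASE` — only the first, preserving the
single-placeholder invariant; (2) `@word` → `@username`; (3) URLs →
`URL`; (4) free-standing `@` → "at"; (5) remaining punctuation deleted in
place ("I'm" → "Im"), keeping the `@` of `@username` and the `#` of
hashtags so those tokens survive tokenization. The result is
whitespace-clean and the function is idempotent on its own output, which
the suite asserts corpus-wide.

Tagging is a pluggable contract (token list → equal-length tag list over a
Penn-Treebank-style inventory). Two taggers ship: a dictionary-lookup
tagger for tests, and a deterministic closed-class/suffix rule tagger used
by default. The rule tagger is not a trained model and makes no accuracy
claim; its value is that pattern statistics are bit-reproducible across
runs and machines, and that any conforming tagger (e.g. a trained Twitter
tagger) can be swapped in without touching the pattern logic.

A context pattern is the tag window `(l, r)` around the placeholder. The
enumeration rule — all shapes with `0 ≤ l ≤ L`, `0 ≤ r ≤ R`,
`|l − r| ≤ 1`, `l + r ≥ 1`, ordered by total width then left width — was
adopted because it grows windows symmetrically, stops one step after a
side is exhausted, yields exactly four patterns for a (2,1) context, and
produces the asymmetric rendered forms (`'DISEASE','NNP'`,
`'NNP','NNP','DISEASE','NNP'`) seen in practice. The rule is isolated in
`admissible_shapes` so alternatives can be swapped and compared. Every
emitted pattern instance is counted; no per-tweet deduplication is applied
before the frequency tables.

## Concept-identifier agreement

External identifiers (UMLS-backed tools in the MetaMap family) are
abstracted to a contract: text → (concept, score) pairs with scores in
(0, 1000]. The agreement statistic is the fraction of concept-bearing
tweets where any identified concept, normalized like a lexicon surface
form, equals any dictionary-matched canonical; it is reported at 2
decimals with full precision retained. Per-tweet relevance is the
*maximum* hit score — the score encodes relevance, and the most relevant
reading is the one a downstream consumer would act on. Collection averages
are reported on two labelled bases (hit-bearing tweets only, and all
collection members), since "average relevance" is ambiguous between them.
A lexicon-backed stand-in identifier (score 1000 for each matched
canonical) supports end-to-end runs and a self-consistency check:
agreement is exactly 1 on corpora whose mentions are canonical forms.

## Synthetic corpus generator

The generator is the package's study design, not a convenience fixture.
Defaults (5 000 messages, seeded):

| parameter | default | meaning |
|---|---|---|
| `frac_news` | 0.20 | news-title tweets, duplicated verbatim |
| `news_dup_factor` | 20 | mean copies per news title |
| `frac_noise` | 0.10 | job-ad / check-in tweets (instantiate the default filter patterns) |
| `frac_mention` | 0.25 | personal tweets embedding one disease term |
| `p_airport`, `p_hospital` | 0.05, 0.04 | probability of POI-proximal placement |
| scatter radii | 1.0 km, 0.1 km | within-fence placement spread (fences are 3 / 0.2 km) |
| catalog | 300 two-word terms | modifier × noun products, uniform prevalence |
| `news_head_frac` | 0.10 | share of the catalog reserved for news titles |

News titles draw terms round-robin from the catalog head (30 terms) and
each title is copied `news_dup_factor` times on average, so every news
term accumulates ≥ ~20 counts; personal tweets draw uniformly from the
270-term tail (~4.6 expected mentions per term), producing a long tail
with singletons. This separation makes the headline phenomenon a testable
property rather than an anecdote: the top decile of the term distribution
is entirely news-planted, and singleton terms are (≥ 90 %) personal.
Coordinates are sampled by exact spherical bearing/distance offset, so the
planted collection labels agree with the haversine fences by construction;
background locations are rejection-sampled outside every fence, and POIs
are placed ≥ 10 km apart so the two fence kinds never overlap. One seed
sequence is split into independent streams (classes, text, geometry) so
enlarging the corpus does not perturb POI placement.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: linguistic variety (texts are templated),
misspellings and fuzzy variants (the matcher is strict by design),
temporal burst structure, user networks and retweet dynamics, polysemy
("knocked-out"-style non-clinical usage), and adversarial noise that the
default patterns miss. Recovery metrics of 1.0 on clean synthetic corpora
certify the plumbing, not real-world recall.

## Pipeline scoring

`evaluate_pipeline` scores outputs against ground truth: mention
recall/precision against planted terms, noise recall against planted
noise, a geofence confusion matrix (planted collection × predicted label)
over the mention-bearing tweets, and estimated class fractions. The news
fraction is estimated by the duplicate-text heuristic — a mention-bearing
tweet whose exact text occurs at least 5 times in the filtered corpus —
the threshold separating title duplication (~20 copies) from chance
template collisions among personal tweets.

## Numerical and testing choices

- Distances validated against the spherical law of cosines at relative
  tolerance 1e-6, restricted to separations above ~1 m where that formula
  is well-conditioned.
- The matcher is validated against a brute-force token-window oracle, and
  the pattern enumerator against brute-force shape enumeration for all
  contexts up to 6 tags per side.
- Class-fraction recovery is asserted within 3-sigma binomial bounds at
  n = 5 000. Per-term counts in the 270-term tail are checked against the
  sampling design with a family-wise bound (the per-term 3-sigma band is
  widened to cover 270 simultaneous comparisons).
- Degenerate inputs: empty POI lists give infinite nearest distances (and
  false membership); an empty tweet tags to an empty sequence; a corpus
  file with > 50 % malformed lines is rejected rather than silently
  truncated; agreement over zero hit-bearing tweets is reported as 0 with
  an explicit degenerate flag.
- Problem sizes in the default suite — 5 000-message study, 10⁴ distance
  pairs, 500 matcher fixtures — keep a full run in the low seconds while
  leaving the binomial bounds tight enough to detect real defects.

## Known limitations

- The rule tagger's tags are coarse; pattern *identities* (which tags
  surround DISEASE) on real text will differ from a trained tagger's.
  Pattern *counts* per tweet do not, which is what the enumeration tests
  certify.
- The strict matcher has no fuzzy matching, negation handling, or
  word-sense disambiguation; agreement with an external identifier is the
  intended guard against polysemy, not the matcher itself.
- The check-in/job regexes are anchored to common templates and will miss
  paraphrases; they are config-overridable by design.
- GeoJSON export rounds coordinates to 6 decimals (~0.1 m), sufficient for
  mapping but not for re-deriving exact fence membership at the boundary.
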