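# Methods

This note documents the models, defaults and design decisions behind
`tweethnic`, and what the synthetic experiments do and do not establish.

## Pipeline model and assumptions

The pipeline assumes a line-delimited JSON stream of tweets (id, user
id, UTC timestamp, text ≤ 140 characters, free-text profile location,
optional coordinates and language tag). The analysis unit is the
per-user timeline: tweets grouped by user id, sorted chronologically
with the tweet id as a deterministic tie-break, and joined with a single
space — the simplest separator that never merges tokens, and the
convention under which the 85-character minimum-length rule is applied.
Month partitioning uses UTC calendar months; the default nine-month
study window spans April 2014 – January 2015 with June 2014 absent
(modelling a collection outage; May and July are partial). No timezone
information is assumed beyond UTC.

### Cleaning cascade

Stages run in a fixed order: (1) whole-tweet removal of tweets matching
a URL (scheme-ful, bare shortener host, or bare `domain.tld` token),
@-mention, or leading retweet marker — removal rather than stripping,
because the remaining fragment of a linking tweet is mostly non-language
filler; (2) aggregate rebuild; (3) timelines with cleaned aggregate
< 85 characters dropped (strictly less: exactly 85 is retained);
(4) non-US profile locations dropped by case-insensitive gazetteer match
(state names, postal abbreviations, country designators, major cities);
an *empty* location is retained — only identifiably non-US users are
excluded; (5) non-English timelines dropped, by majority `lang` tag when
tags exist, otherwise by an ASCII-dominance heuristic adequate for the
synthetic corpora; the detector is a pluggable predicate for anything
better. The cascade is idempotent and every stage reports an audit
count; the counts conserve the input tweet total. A known limitation of
the gazetteer is that lower-cased two-letter state abbreviations
collide with common English words; this matters only for free-text
locations like "somewhere in Europe" and is accepted for location
*fields*, which are short and formulaic.

### Self-declaration labels

The template inventory is the cross-product of copula frames
(`I am …`, `I'm …`, `I am a/an … man/woman`, `I'm a/an … man/woman`)
with ethnic terms (white, Caucasian → Caucasian; black,
African-American, African American → AfricanAmerican; Asian → Asian;
Hispanic, Latino, Latina → Hispanic), matched case-insensitively at word
boundaries within individual tweets. The inventory is closed and
configurable — no claim is made that it exhausts real self-identifying
language; it is a documented default. Race and ethnicity terms are
deliberately not distinguished beyond the four keys. Users whose
declarations disagree are excluded rather than resolved by vote, since
self-statements are not reliably consistent. Matched spans are excised
from the feature text by default (masking on) so the declaration cannot
leak into the classifier; masking can be turned off to measure the
leakage.

### Representations

*Tokenization* lowercases, strips punctuation, and keeps underscores so
multi-word synonyms stay single columns. *Stemming* is the classic
five-step Porter algorithm applied to convergence, which makes the stem
map a projection (`stem(stem(t)) = stem(t)` for every token). A single
Porter pass is already a fixed point for almost all English words; the
iteration only shortens a few residual forms further (e.g. the latinate
plural "metastases" → "metastas" → "metasta") and was chosen so that
stem identity is stable no matter how often text passes through the
featurizer.

*Synonym expansion* appends, per tweet, the top-k (default 5) synonyms
of each token tagged noun or verb, at the end of the tweet in token
order then rank order — end-append keeps the original text recoverable
and the original token sequence a prefix of the expanded one. The
part-of-speech tagger and the synonym source are pluggable contracts.
The default tagger is rule-based (closed-class function words → other;
common verbs and verbal suffixes → verb; else noun); its precision
matters little because only tokens with a lexicon entry trigger an
expansion. The default synonym source is a JSON lexicon; the bundled
`synonyms_synthetic.json` is a *synthetic* lexicon constructed jointly
with the corpus generator (it links each signature variant to its
concept siblings plus a few everyday synonym sets). Any richer lexicon
with the same `(lemma, pos) → ranked list` contract can be dropped in.
Ranking is delegated to the source's native order; multi-word synonyms
are joined with underscores.

*Document-term matrix.* Counts are computed after optional expansion and
stemming; columns with document frequency < 2 are pruned by default to
bound vocabulary growth (configurable; `min_df=1` disables pruning and
conserves token mass exactly). Stop-words are retained: function-like
tokens carry group signal in this problem and no stop list is part of
the method.

*Topics.* LDA is fitted on user-aggregated records only — never on
single tweets — with symmetric priors (document-topic 1/K, topic-word
0.01), batch variational inference, a 30-iteration budget and a fixed
seed. K defaults to 45; `select_k` sweeps an increasing grid, scoring
each K by pooled cross-validated classification accuracy, and breaks
ties toward the smallest K (parsimony). Topic vectors are renormalized
to sum to one; an all-zero document maps to the prior mean (uniform)
simplex. The K-topic representation reduces the feature count by
`1 − K/|V|` relative to the vocabulary.

### Classification and evaluation

The classifier is an RBF-kernel SVM (C = 1, data-scaled gamma). No
class weighting is applied by default: on imbalanced training data the
unweighted decision function over-predicts majority classes, which is
the documented behaviour of the method this package implements;
inverse-frequency weighting is available as an option. Cross-validation
uses ten seeded random bins whose sizes differ by at most one,
non-stratified by default ("equally sized bins"), with stratification
available — the pipeline uses it because small synthetic labeled sets
otherwise risk a class-free training split, which is reported as an
error advising stratification. The confusion matrix pools all folds;
every example is predicted exactly once. Balanced accuracy is the
one-vs-rest mean of sensitivity and specificity, reported in percent; a
constant predictor scores exactly 50% for every class. Prediction of
undeclared users is a total function (no abstention) and requires
representations built with the training vocabulary / topic model.

### Surveillance

Lexicon phrases are matched case-insensitively at token boundaries
("scancer" never matches), longest phrase first and non-overlapping, so
"breast cancer" counts once in the breast lexicon even though it embeds
"cancer". Plural shorthands `(s)` and optional articles `(the)` are
expanded at load; the one duplicated entry in the shipped general list
is deduplicated. The general unigram lexicon is retained without
context disambiguation (zodiac vs disease); a context-filter hook would
slot in at `count_mentions` but ships disabled, since the unigram is
kept for comparison only and the site-specific bigrams are unambiguous.

Normalization divides a group's monthly mention count by its *active
users* that month (≥ 1 retained tweet), making cross-group comparison
population-size-free; the alternative reading (count ÷ group percentage)
is a configuration away because the underlying counts and margins are
all in the usage table. Significance testing uses the two-sided Welch
(unequal-variance) t-test on per-user monthly totals — group sizes and
variances are grossly unequal, so the pooled-variance test would be
anti-conservative. Months are tested independently, without
multiple-comparison adjustment, at α = 0.05. Degenerate inputs are
defined: two identical constant samples give t = 0, p = 1; samples with
fewer than two users are an error. The campaign-drop baseline defaults
to the mean of the two window months preceding the campaign month, and
is configurable.

## The synthetic-corpus generator

The generator emulates the statistical features the pipeline is
sensitive to: four groups drawn at stream-population shares (92.32 /
7.12 / 0.28 / 0.28 percent by default — classification experiments
override these with labeled-set shares of roughly 45 / 32 / 10 / 12
percent, since the self-declared subpopulation is far less imbalanced
than the stream); group-conditional unigram vocabulary signatures mixed
into a shared Zipf-weighted vocabulary at `signature_strength` (default
0.7); verbatim self-declarations at `declaration_rate` (default 0.05);
URL/mention/retweet noise at 10/8/5 percent per tweet from the exact
pools the cleaning patterns target; 5 percent non-US profile locations;
and per-month, per-group, per-category Poisson cancer-phrase injection
with a 3× awareness-month spike and a steeper minority-group fall in
the month after the campaign. Timeline length defaults (tweets per user
2 + Poisson(7), tokens per tweet 2 + Poisson(5)) were calibrated once so
the mean *cleaned* aggregate is ≈ 324 characters. A fixed seed yields
byte-identical corpora.

Signature vocabulary is arbitrary neutral token sets (tree, bird,
colour, instrument, landform and verse-form words) — deliberately *not*
a model of any group's actual language. Each signature concept has
three interchangeable surface variants linked in the bundled synonym
lexicon, and each user adopts one variant per concept, producing the
within-group lexical variation that synonym expansion is designed to
bridge.

What the generator does **not** emulate: n-gram syntax or any linguistic
realism beyond unigram frequencies (the downstream methods are
bag-of-words/LDA, so unigram structure is sufficient for testing them),
social-graph structure, retweet cascades, topic drift, adversarial or
ironic self-description, code-switching, or real dialect variation.
Consequently, passing tests demonstrate that the pipeline's machinery is
correct and that its statistics are calibrated — not that the
classifier would reach comparable accuracy on real timelines, where the
signal is weaker and self-declarations are noisier.

## Experimental designs in the acceptance surface

* **Recovery**: 2000 users at labeled-set shares, signature strength
  0.7, declarations on half the users; pooled ten-fold CV on the
  expanded representation must exceed 90% pair accuracy on the two
  majority groups (it reaches ~100% — the planted signal is strong by
  construction).
* **Expansion advantage**: the expanded-vs-plain comparison is run on
  sparse timelines (1 + Poisson(2) tweets of 2 + Poisson(3) tokens,
  signature strength 0.25). At full-length, high-signal conditions both
  representations saturate and the comparison degenerates to
  one-example tie noise; in the sparse regime each user exhibits only a
  few of their group's synonym variants, the variant split costs the
  plain bag of words ~15 accuracy points, and expansion recovers them.
  This is the regime the representation was designed for.
* **Calibration**: 200 single-month replicates (80 users, equal
  injection of 1 mention/user between two groups) give a Welch
  rejection rate at α = 0.05 inside the binomial 95% band around 0.05.
* **Drop recovery**: a flat 0.3 mentions/user/month breast series with a
  5× October spike and a November rate of 0.09 (a configured 70% drop
  against the August–September baseline) is recovered within ±10
  percentage points; the small systematic shortfall (~1–3 points) comes
  from the active-user denominator, which injection tweets themselves
  perturb slightly.

Problem sizes throughout (hundreds to a few thousand users) were chosen
as the smallest at which the measured quantities are stable across
seeds.

## Known limitations

* The four-key label scheme cannot represent mixed or multi-racial
  identity, and the template inventory is a small closed set.
* The default English detector is a heuristic; real multilingual streams
  need a proper detector behind the pluggable contract.
* The bundled synonym lexicon is synthetic; results with a real
  lexical database will depend on its sense ordering.
* The SVM is the only classifier exercised; others can stand behind the
  same contract but are untested.
* Surveillance counts are term-level: no word-sense disambiguation, no
  negation handling, no sarcasm.
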