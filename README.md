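# tweethnic

Infodemiology toolkit for **inferring Twitter users' race/ethnicity from
their timelines** and **quantifying racial/ethnic differences in
cancer-term usage over calendar months**.

Public-health surveillance on social media needs demographic context
that platforms do not provide. This package implements a text-mining
pipeline that (1) reconstructs per-user timelines from a tweet stream,
(2) mints training labels from first-person self-declarations
("I am African-American", "I'm Asian", "I'm a black man"), (3) classifies
the remaining users from their aggregated writing records, and
(4) tabulates monthly usage of cancer keyword lexicons by group, with
significance tests and awareness-campaign drop statistics. Because raw
Twitter streams cannot be redistributed, a first-class synthetic-corpus
generator with known ground truth makes every stage reproducible and
testable offline.

## The method

**Unit of analysis.** A *timeline* is the chronologically ordered
collection of one user's tweets (each ≤ 140 characters), aggregated into
a single writing record. Aggregation is what makes short-text
classification and topic modeling workable.

**Cleaning.** Tweets containing non-language linking elements (URLs,
@-mentions, `RT @user` markers) are removed whole; timelines whose
cleaned aggregate is shorter than 85 characters are dropped, then
non-US-profile and non-English users.

**Labels.** A closed template inventory of copula frames × ethnic terms
(`I am …`, `I'm a … man/woman` × white/Caucasian, black/African-American,
Asian, Hispanic/Latino/Latina) maps each declared user to one of four
group keys; conflicting declarations exclude the user, and matched spans
are masked out of the feature text so the label cannot leak.

**Representations.** Two competing timeline representations feed an
RBF-kernel SVM:

* *synonym-expanded bag of words* — Porter-stemmed term frequencies
  where the top five synonyms of every noun and verb are appended to
  each tweet first, increasing lexical overlap between users who express
  the same concept with different words;
* *LDA topics* — each aggregated record compressed to a K-simplex of
  topic proportions (K = 45 by default, selectable by a cross-validated
  accuracy sweep).

**Evaluation.** Pooled ten-fold cross-validation produces a confusion
matrix C with rows = predicted class and columns = reference class.
For class *i* with reference total `n_i` and N examples overall:

```
sensitivity_i = C_ii / n_i
specificity_i = (N - n_i - FP_i) / (N - n_i),   FP_i = Σ_j≠i C_ij
balanced accuracy_i = (sensitivity_i + specificity_i) / 2
overall accuracy   = trace(C) / N
pair accuracy(S)   = overall accuracy of C restricted to classes in S
```

**Surveillance.** Five cancer lexicons (general vocabulary plus breast,
colorectal, lung, prostate phrase lists) are matched case-insensitively
at token boundaries, longest phrase first. Counts per month × group are
normalized per active user; group differences in per-user monthly totals
are tested with two-sided Welch t-tests (no multiplicity adjustment,
α = 0.05); the *campaign drop* after an awareness month (Prostate =
September, Breast = October, Lung = November) is
`100 × (mean baseline − following-month rate) / mean baseline`.

## Worked example

```python
import tweethnic as tw
from tweethnic.corpus import Group

cfg = tw.PipelineConfig(
    synthetic=tw.SyntheticCorpusConfig(
        n_users=500, declaration_rate=0.4,
        group_proportions={Group.CAUCASIAN: 0.452,
                           Group.AFRICAN_AMERICAN: 0.323,
                           Group.ASIAN: 0.102, Group.HISPANIC: 0.123}),
    representations=("expanded", "topics"), seed=7)
manifest = tw.run_pipeline(cfg, "run")
print(manifest["stages"]["evaluate"])
```

prints

```
{'expanded': {'overall': 100.0, 'pair': 100.0},
 'topics':   {'overall': 95.3757, 'pair': 100.0}}
```

i.e. on this 500-user corpus the pipeline retained 473 timelines after
cleaning (919 of 5321 tweets dropped for linking elements, 25 users
dropped as non-US), extracted 173 self-declared training labels with no
conflicts, and cross-validated both representations: the
synonym-expanded bag of words classifies every declared user correctly
while the 45-topic representation reaches 95.4% overall — the same
ordering the method reports on real data, where lexical nuance lost in
topic compression costs accuracy. `run/` then holds the confusion
matrices, monthly usage table, Welch-test results and a `manifest.json`
whose config hash and counts are bit-identical across reruns with the
same seed.

The same pipeline is available from the shell:

```bash
tweethnic run-all --n-users 500 --seed 7 --outdir run
tweethnic simulate --n-users 200 --seed 1 --out corpus.jsonl
tweethnic preprocess corpus.jsonl --min-chars 85 --out clean.jsonl
tweethnic label clean.jsonl --out labels.csv
tweethnic surveil corpus.jsonl corpus.truth.csv --lexicon breast --out usage.csv
```

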