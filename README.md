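# credfilter

Expert-time triage for medical-misinformation annotation.

Assessing the credibility of online health content needs trained medical
experts, and expert time is the scarcest resource in any fact-checking or
annotation pipeline. `credfilter` implements a filtering framework that
makes better use of that time: per-topic classifiers score short text
units, and the units confidently predicted *credible* are removed from the
expert annotation queue, so the experts spend their limited hours mostly
on content that is likely non-credible. It is aimed at research groups
running sentence-level credibility annotation campaigns (and anyone
studying precision-constrained triage of annotation queues).

## Method

Sentences carry one of three expert labels: **CRED** (credible), **NEU**
(neutral — no medical factual content), **NONCRED** (non-credible).
Because credibility judgments often need surrounding context, the
classification unit is the **triplet**: three consecutive,
non-overlapping sentences of one article. Labels propagate as

- *negative* ⇔ any member is NONCRED,
- *positive* ⇔ all members are CRED or NEU.

Per topic, the pipeline is:

1. **Features.** One lexical family per run — uncased lemma TF-IDF
   (smoothed idf, L2 rows) *or* ingested embedding vectors — plus
   stylometric families: dependency-relation counts, POS counts,
   named-entity counts, polarity/subjectivity, and LIWC-style category
   lexicon rates. All features are standardized to unit variance;
   everything partition-dependent is fitted on training folds only.
2. **Feature selection.** Backward recursive feature elimination driven
   by absolute logistic-regression coefficients, capped at 30% of the
   topic's sample count.
3. **Model search.** A seeded exhaustive grid over logistic regression,
   gradient-boosted trees (XGBoost) and a multilayer perceptron, scored
   by mean cross-validated F1 of the positive class, producing
   out-of-fold probabilities p̂(positive) for every triplet.
4. **Cutoff selection.** A threshold *t* on p̂ is chosen to maximize the
   negative share below *t* relative to the topic baseline, with minimal
   fold-to-fold variance, subject to positive precision ≥ 0.9 above *t*,
   preferring cutoffs that filter more.
5. **Reporting.** *Baseline utilization* = % negative in the whole topic;
   *optimized utilization* = % negative below the cutoff; reported with
   their percentage-point difference and ratio (improvement factor),
   alongside expert-throughput arithmetic (statements/day = effective
   working seconds ÷ mean evaluation seconds).
6. **Explanations.** Global coefficient rankings for the linear family,
   and an in-repo local surrogate (perturbation + proximity kernel +
   weighted ridge on the model's log-odds) for any probabilistic model;
   plus feature-family share and cross-topic overlap reports.

A seed-deterministic synthetic-corpus generator (three-class persistent
label chains, class-marker unigram text, stylometric deltas, lognormal
annotation times, per-class context-need rates) makes the whole pipeline
testable offline, with a closed-form oracle for the induced
triplet-negative rate: at persistence ρ=0 it is 1 − (1 − p)³ for
sentence-level non-credible probability p.

## Worked example

Generate one synthetic topic (about 18% non-credible sentences, marker
elevation ratio 3), train the filtering classifier and pick the cutoff:

```python
import numpy as np
from credfilter.synthetic import TopicConfig, GeneratorConfig, generate_triplets
from credfilter.features import assemble_features
from credfilter.selection import encode_labels, make_folds, model_search, evaluate_roc
from credfilter.cutoff import candidate_statistics, select_cutoff, utilization_report

trips = generate_triplets(TopicConfig(name="heart-supplements"), 600,
                          config=GeneratorConfig(elevation_ratio=3.0), seed=7)
y = encode_labels([t.binary_label for t in trips])
X = assemble_features(trips)
folds = make_folds(y, seed=7)
config, oof, board = model_search(
    X, y, folds, grids={"regularized-linear": [{"C": 0.1}, {"C": 1.0}, {"C": 10.0}]}, seed=7)
_, auc = evaluate_roc(oof, y)
chosen, feasible = select_cutoff(candidate_statistics(oof, y), float(np.mean(y == 0)))
rep = utilization_report(y, oof, chosen.t)
```

which prints, via the report fields:

```
winner: regularized-linear {'C': 0.1}, folds k=10, AUC = 0.870
cutoff t = 0.824 (feasible: True)
baseline utilization  = 33.3%
optimized utilization = 61.8%
improvement = 28.4 pp (factor 1.9)
positive precision above cutoff = 0.902; 54.7% of triplets filtered out
```

Reading: without filtering, an expert annotating this topic would see a
non-credible triplet 33.3% of the time; after removing the 54.7% of
triplets the classifier confidently calls credible (only 9.8% of which
are actually negative), the expert's queue is 61.8% non-credible — about
1.9× more misinformation found per hour of expert time.

The same flow is available from the shell:

```bash
credfilter simulate --preset small --seed 7 --out corpus.csv
credfilter run --corpus corpus.csv --outdir run7 --seed 7
```

which writes the triplet table, out-of-fold predictions, the per-topic
utilization table, partition summaries, throughput and explanation
reports, and a log of all resolved settings into `run7/`.

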