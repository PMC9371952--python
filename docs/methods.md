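# Methods

This note documents the models, numerical choices and open design
decisions behind `credfilter`, and what the synthetic benchmarks do and
do not show about real annotation campaigns.

## Problem setting and assumptions

The package models an annotation campaign in which medical experts label
sentences of online health articles as credible (CRED), neutral (NEU) or
non-credible (NONCRED), and in which expert hours are the binding
constraint. The quantity being optimized is *utilization*: the
probability that the next item an expert annotates is non-credible.
Filtering works only under two assumptions: (i) topics are narrow and
known in advance (classifiers are trained per topic; pooled models are
known to degrade to chance on this task), and (ii) a false "credible"
prediction is tolerable at a controlled, low rate — filtered-out
misinformation is never seen by an expert, which is the method's
irreducible cost.

## Triplets and label propagation

Sentences are grouped, within one article and in position order, into
consecutive non-overlapping triplets — positions (0,1,2), (3,4,5), … —
to give classifiers the context annotators themselves needed (roughly a
quarter of non-credible sentences required at least one surrounding
sentence to judge). A triplet is negative iff any member is NONCRED.
The trailing one or two sentences of an article are dropped by default;
a `pad` option repeats the last sentence instead, because dropping loses
up to two labels per article. Triplets never cross article boundaries.
Exact enumeration of the 3³ = 27 label combinations gives 19 negative
outcomes (all but the 2³ all-{CRED,NEU} ones); this is frozen as a test.

## Feature families

* **TF-IDF** (lexical): uncased, optionally lemmatized tokens;
  smoothed idf ln((1+N)/(1+df))+1, L2-normalized rows, `min_df=2`.
  The variant is fixed because coefficient-based selection needs one
  canonical scaling; `min_df` keeps vocabulary sizes near the
  low-thousands range typical of per-topic corpora of this size.
* **Embedding vectors** (lexical alternative): ingested from file, never
  computed — contextual-embedding inference is out of scope and the
  dimensions are treated as opaque. Exactly one lexical family per run.
* **DEP / POS / NER** counts: pluggable taggers. The bundled defaults
  are deterministic rule-based taggers (closed-class word lists + suffix
  rules; relations derived from the tag stream; gazetteer + digit regex
  for entities over {PERSON, ORGANIZATION, PRODUCT, NUMBER}). They trade
  accuracy for determinism and zero downloads; any real tagger with the
  same `text -> list of tags` signature can be plugged in. Exclamation
  marks get their own tag (EXCL): they are a standard stylometric cue,
  and folding them into PUNCT would hide them entirely because every
  sentence contributes exactly one terminal mark.
* **SENT**: polarity = mean signed score of matched polarity-lexicon
  words in [-1, 1] (0 when none match); subjectivity = fraction of
  tokens in the subjectivity lexicon. Small open lexicons are bundled.
* **LEXICON**: category word counts in the percent-delimited dictionary
  dialect, with terminal `stem*` wildcards. Output defaults to
  percentages of token count (the convention of word-count category
  tools); raw counts are available. A ~15-category open fixture lexicon
  ships with the package so nothing proprietary is required; a licensed
  dictionary in the same format drops in via
  `CategoryLexicon.from_liwc_file`.

Standardization to unit variance is a separate, explicit step: the raw
matrix keeps TF-IDF rows L2-normalized; `standardize_features` (or the
featurizer's default) produces the unit-variance matrix, recording the
per-column mean/sd and the rows they were fitted on. Constant columns
are centered but not scaled.

### Leakage control

`TripletFeaturizer.fit` learns everything partition-dependent (TF-IDF
vocabulary/idf, stylometric column sets, standardization) from the
training rows only; `transform` maps any rows into exactly that space.
In the default *honest* pipeline mode these statistics — and the feature
selection — are refit inside every training fold, so out-of-fold
probabilities never reflect held-out rows. Stylometric extractors are
stateless per text and are cached, so fold-wise refits cost only the
TF-IDF/standardization/RFE work. A non-honest mode (single shared
matrix) exists for exploration and ablation.

## Feature selection and model search

Recursive feature elimination uses a regularized logistic model, removes
the lowest-|coefficient| feature each iteration (step 1 by default;
a larger or fractional step is available for wide matrices), and stops
at floor(0.3 × n_samples) features — the 30% cap ties model capacity to
topic size.

The model search is a deterministic seeded grid over three families —
regularized-linear, gradient-boosted-trees, multilayer-perceptron —
rather than an evolutionary AutoML search: reproducibility is worth more
here than search breadth, and the per-family grids are deliberately tiny
(≤ 12 points) so full runs stay in minutes. Candidates are scored by the
mean per-fold F1 of the *positive* class (the class being filtered;
which F1 variant drives selection is genuinely open — positive-class F1
is the choice consistent with the filtering objective). Exact ties break
toward the simpler family (linear < trees < perceptron), then the
earlier grid point. Fold counts default to clamp(floor(n/50), 3, 10),
stratified and seeded; the rule is an invented default capturing
"folds grow with topic size".

## Cutoff selection

For each threshold t over the out-of-fold probabilities (default grid:
all unique probabilities plus probes {0.5, 0.9, 0.95, 0.97, 0.99};
thresholds leaving either side empty are excluded), three statistics are
computed: the fold-wise mean and sd of the negative share below t, the
pooled positive precision at/above t, and the above-count. The three
selection criteria (gain over baseline with minimal variance; high
positive precision; many samples filtered) are combined as a
**floor-constrained, variance-penalized objective**: among candidates
with positive precision ≥ 0.9, maximize
(mean_below_neg − baseline) − λ·sd_below_neg (λ = 1), ties to the larger
above-count, then the smaller t. If no candidate meets the floor, the
highest-precision candidate is returned flagged infeasible. The 0.9
floor reflects the >90% positive precision regime the method targets;
floor, λ and the tie-breaks are all configurable because the combination
rule (as opposed to the three criteria) is a design choice of this
package.

Utilization is reported on the 0–100 scale; the improvement factor is
optimized/baseline rounded half-up to one decimal (half-up reproduces
printed one-decimal reporting, e.g. 64.9/44.7 = 1.4519 → 1.5). The
conservation identity baseline = w·below_neg + (1−w)·above_neg (w the
below-fraction) holds to 1e-9 by construction and is fuzz-tested.

## Throughput arithmetic

Effective seconds = hours × (60 − break minutes per hour) × 60; the
defaults (8 h, 15 min/h → 21 600 s, i.e. six effective hours) model a
realistic expert workday. Statements/day and articles/day use floor
division (21 600/35 = 617.14 → 617), and statements/article defaults to
40 ≈ round(10 000 statements / 247 articles). Per-topic time summaries
ignore sentences without a recorded time and report the count used.

## Explanations

Coefficient explanations are restricted to the linear family on
standardized features (otherwise magnitudes are incomparable); signs are
preserved, positive leaning credible; zero weights are dropped.

The local surrogate is implemented in-repo so it is seedable and
testable against a linear glass-box. Design: n perturbations of the
instance (per column, probability 0.5 of perturbing; lexical columns are
masked to zero — a masked word is an absent word — while stylometric
columns are resampled from their training marginal); neighbours weighted
by exp(−d²/σ²) on cosine distance with σ = 0.25·√d (d = feature count);
a ridge model (α = 1) fitted to the black-box **log-odds** (clipped at
1e-6). Fitting the log-odds rather than the probability makes the
surrogate exactly recover a linear model's coefficients, which is the
package's main self-consistency check. The reported *weight* of a
feature is its surrogate coefficient; its *contribution* is
weight × (x_j − training mean of column j), and features are ranked by
absolute contribution — so an instance at the data centroid (e.g. the
all-zero standardized vector) correctly receives ≈0 contributions even
where the surrogate slope is nonzero.

Family-share tables collapse TF-IDF/embedding columns onto one "lexical"
family and report percentage shares per topic; the cross-topic overlap
report counts, for each non-lexical feature, the topics whose
important-feature list contains it, dropping singletons. Which
"important" set feeds these reports is ambiguous in principle; the
pipeline uses the RFE-selected set for TF-IDF runs and the top-k
coefficient set for embedding runs (configurable).

## Synthetic corpora

The generator emulates the statistical structure the pipeline assumes,
not natural language:

* **Labels**: per article, a first-order persistence chain — with
  probability ρ repeat the previous class, else draw from the topic's
  class probabilities (ρ = 0 ⇒ iid). The chain is the simplest mechanism
  giving within-article clustering of non-credible sentences, which real
  corpora show (triplet-level negative rates deviate from the iid
  formula). Defaults: class probabilities (0.55, 0.266, 0.184), ρ = 0.5.
* **Text**: 14–26 background unigrams per sentence (zipf-weighted
  generic vocabulary) mixed with class-marker tokens: each non-own class
  pool is drawn at `marker_rate` = 0.08 per token, the own-class pool at
  `marker_rate × elevation_ratio` (default ratio 3). Non-credible
  stylometric deltas — certainty words (base 0.02/token), terminal
  exclamation marks (base 0.1/sentence), organization mentions (base
  0.015/sentence) — default to base × elevation_ratio, so ratio 1 means
  no signal of any kind and the single ratio dial scales lexical and
  stylometric signal together. These defaults were chosen so that the
  dial spans chance (AUC ≈ 0.5 at ratio 1) to clearly learnable
  (AUC ≥ 0.8 and ≥ +10 pp utilization gain at ratio 3 on 600 triplets),
  the regime in which the pipeline's behaviour is asserted.
* **Times**: lognormal with configured topic mean (σ = 0.6), matching
  long-tailed per-statement evaluation times with topic means in the
  18–35 s range. **Context depth** is sampled per class from
  realistic context-need distributions (≈80/19/1% for credible
  sentences, more context needed for non-credible ones).
* **Oracle**: the expected triplet-negative rate is available in closed
  form: 1 − (1−p)³ at ρ = 0, and by enumeration of the 3-step chain for
  ρ > 0 (the 27 label paths collapse onto 8 paths of the 2-state
  NONCRED/other chain, whose stationary start is (p, 1−p)); it is
  strictly decreasing in ρ (clustering concentrates negatives into fewer
  triplets).

Ten topic presets mirror a published ten-topic corpus's class-count
mixes and time range; they are presets for realistic simulation, not
claims about any dataset.

**What passing synthetic tests shows** — that every pipeline stage is
wired correctly, leak-free, seeded, and that the cutoff machinery
converts real class signal into utilization gains at controlled
precision. **What it does not show** — performance on real prose:
unigram mixtures carry no syntax, so dependency/POS features are only
weakly informative here, the rule-based taggers are not accuracy-matched
to trained parsers, and real topical signal is semantically loaded in
ways markers only caricature. Reported per-topic improvements on real
data are therefore treated as reference inputs (see
`credfilter.reference`), never as quantities the generator should
reproduce per topic.

## Numerical and degenerate-input choices

* Fold-wise below-cutoff statistics use population sd (ddof 0) over the
  folds with a non-empty below side; pooled values are used where fold
  information is absent (sd reported as 0).
* `make_folds` refuses single-class input and k above the minority class
  count, rather than silently shrinking k.
* Empty documents produce zero TF-IDF rows; fully out-of-vocabulary
  documents likewise; both survive standardization (constant columns are
  never divided by zero).
* Probabilities are clipped at 1e-6 before the surrogate's logit.
* Seeds: every stochastic stage takes an explicit seed; the pipeline
  derives per-topic substreams from the run seed (stable mod-2³¹
  arithmetic) so topics can be rerun independently yet reproducibly.

## Problem sizes used in the checks

Statistical assertions run at sizes chosen for tight-but-honest bounds:
3-standard-error bands at n = 2 000–20 000 for generator rates, 20-seed
repetition for the selection and end-to-end properties (allowing the
1–2 failures the binomial bands imply), 600-triplet topics for the
end-to-end runs, and 5 replicate end-to-end runs in the acceptance
script. Larger corpora sharpen nothing qualitative in these checks.

## Known limitations

* The rule-based taggers are caricatures of real parsers; DEP/POS/NER
  shares in family reports are meaningful only relative to the tagger
  used.
* The local surrogate assumes feature-space perturbation is meaningful;
  for embedding columns, masking a dimension to zero has no linguistic
  interpretation (the dimensions are opaque by design).
* Cutoffs are selected on out-of-fold predictions of the same data used
  to pick the model; a fully unbiased utilization estimate would need a
  further held-out split, which per-topic sample sizes rarely afford.
* Annotator disagreement is not modelled (one expert per sentence), and
  probability calibration is out of scope — cutoffs are chosen on the
  empirical probability scale, not a calibrated one.
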