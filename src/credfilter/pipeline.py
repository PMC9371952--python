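"""End-to-end orchestration: corpus -> triplets -> features -> models ->
cutoffs -> reports -> explanations.

The default pipeline mode is *honest*: everything partition-dependent —
TF-IDF vocabulary and idf weights, standardization statistics and the
recursive feature elimination — is refit inside each training fold, so
out-of-fold probabilities never leak held-out information.  Feature
selection runs once per fold (it depends on the features and labels, not
on the downstream model family) and its column subset is shared by every
candidate model evaluated on that fold.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .corpus import (
    Corpus,
    Triplet,
    build_triplets,
    read_corpus,
    write_corpus,
    write_triplets,
)
from .cutoff import (
    CutoffReport,
    candidate_statistics,
    partition_summary,
    select_cutoff,
    utilization_report,
    utilization_table,
)
from .explain import (
    Explanation,
    coefficient_importance,
    cross_topic_overlap,
    family_share_table,
)
from .features import FeatureConfig, TripletFeaturizer, assemble_features
from .selection import (
    MODEL_FAMILIES,
    FoldAssignment,
    ModelConfig,
    OOFPredictions,
    default_grids,
    encode_labels,
    evaluate_roc,
    make_folds,
    model_search,
    rfe_select,
)
from .synthetic import GeneratorConfig, default_presets, generate_corpus, small_preset
from .throughput import WorkdayModel, articles_per_day, statements_per_day, time_summary

__all__ = ["RunConfig", "PipelineError", "TopicResult", "honest_search", "run_pipeline"]

logger = logging.getLogger("credfilter")


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and its cause."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    corpus_path: str | None = None
    preset: str | None = None  # 'small' | 'default' (used when corpus_path is None)
    outdir: str = "credfilter-run"
    seed: int = 0
    lexical: str = "tfidf"
    embeddings_path: str | None = None
    min_df: int = 2
    use_rfe: bool = True
    rfe_fraction: float = 0.3
    rfe_step: float = 1  # >=1: features per iteration; <1: fraction per iteration
    k_folds: int | None = None
    families: tuple[str, ...] = ("regularized-linear",)
    honest: bool = True
    pos_precision_floor: float = 0.9
    cutoff_lambda: float = 1.0
    top_k: int = 16
    remainder: str = "drop"
    min_triplets: int = 30

    def __post_init__(self) -> None:
        if self.corpus_path is None and self.preset is None:
            raise PipelineError("config error: provide a corpus path or a generator preset")
        unknown = set(self.families) - set(MODEL_FAMILIES)
        if unknown:
            raise PipelineError(f"unknown model families: {sorted(unknown)}")

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            lexical=self.lexical,
            min_df=self.min_df,
            embeddings_path=self.embeddings_path,
        )


def _topic_seed(seed: int, index: int) -> int:
    return int((seed * 1009 + 31 * index + 7) % (2**31 - 1))


@dataclass
class TopicResult:
    """Everything the pipeline computed for one topic."""

    topic: str
    triplets: list[Triplet]
    labels: list[str]
    folds: FoldAssignment
    best_config: ModelConfig
    oof: OOFPredictions
    leaderboard: pd.DataFrame
    auc: float
    cutoff_report: CutoffReport
    cutoff_feasible: bool
    selected_specs: list
    explanation: Explanation | None


def honest_search(
    triplets: Sequence[Triplet],
    labels: Sequence[str],
    folds: FoldAssignment,
    feature_config: FeatureConfig,
    grids: dict | None = None,
    rfe_fraction: float | None = 0.3,
    rfe_step: float = 1,
    seed: int = 0,
) -> tuple[ModelConfig, OOFPredictions, pd.DataFrame]:
    """Grid search with per-fold refit of features and feature selection.

    For each fold: fit the featurizer on the training rows, run capped
    RFE on the training matrix (once — shared by all candidate models),
    then fit every candidate and score the held-out rows.  The candidate
    with the best mean positive-class F1 wins; ties break toward the
    simpler family, then the earlier grid point.
    """
    from sklearn.metrics import f1_score

    y = encode_labels(labels)
    grids = grids if grids is not None else default_grids()
    candidates = [
        ModelConfig(family=family, hyperparameters=tuple(sorted(hp.items())), seed=seed)
        for family in MODEL_FAMILIES
        if family in grids
        for hp in grids[family]
    ]
    if not candidates:
        raise PipelineError("stage search: the grid is empty")

    triplets = list(triplets)
    n = len(triplets)
    probs = {c: np.full(n, np.nan) for c in candidates}
    f1s: dict[ModelConfig, list[float]] = {c: [] for c in candidates}
    models: dict[ModelConfig, dict[int, object]] = {c: {} for c in candidates}

    for f in range(folds.k):
        train_mask, test_mask = folds.train_test(f)
        train_idx = np.where(train_mask)[0]
        test_idx = np.where(test_mask)[0]
        train_triplets = [triplets[i] for i in train_idx]
        featurizer = TripletFeaturizer(feature_config).fit(train_triplets)
        X_train = featurizer.transform(train_triplets)
        X_test = featurizer.transform([triplets[i] for i in test_idx])
        cols = slice(None)
        if rfe_fraction is not None:
            n_target = max(1, int(rfe_fraction * len(train_idx)))
            if n_target < X_train.n_cols:
                selected = rfe_select(
                    X_train, y[train_idx], n_target=n_target, step=rfe_step, seed=seed
                )
                keep = {(s.family, s.name) for s in selected}
                cols = [i for i, s in enumerate(X_train.specs) if (s.family, s.name) in keep]
        Xtr = X_train.values[:, cols]
        Xte = X_test.values[:, cols]
        for config in candidates:
            est = config.make_estimator()
            est.fit(Xtr, y[train_idx])
            pos = int(np.where(est.classes_ == 1)[0][0])
            p = est.predict_proba(Xte)[:, pos]
            probs[config][test_idx] = p
            f1s[config].append(
                f1_score(y[test_idx], (p >= 0.5).astype(int), pos_label=1, zero_division=0)
            )
            models[config][f] = est

    best: tuple[float, ModelConfig] | None = None
    rows = []
    for config in candidates:
        score = float(np.mean(f1s[config]))
        rows.append(
            {"family": config.family, "hyperparameters": dict(config.hyperparameters),
             "mean_f1": score}
        )
        if best is None or score > best[0]:
            best = (score, config)
    winner = best[1]
    oof = OOFPredictions(
        ids=[t.triplet_id for t in triplets],
        fold_of=folds.fold_of,
        p_positive=probs[winner],
        models=models[winner],
    )
    leaderboard = pd.DataFrame(rows).sort_values("mean_f1", ascending=False, kind="stable")
    return winner, oof, leaderboard.reset_index(drop=True)


def _resolve_corpus(config: RunConfig) -> tuple[Corpus, bool]:
    if config.corpus_path is not None:
        return read_corpus(config.corpus_path), False
    if config.preset == "small":
        gen = small_preset(seed=config.seed)
    elif config.preset == "default":
        gen = GeneratorConfig(topics=default_presets(), seed=config.seed)
    else:
        raise PipelineError(f"unknown preset {config.preset!r}; use 'small' or 'default'")
    corpus, _ = generate_corpus(gen, seed=config.seed)
    return corpus, True


def process_topic(
    topic: str,
    triplets: list[Triplet],
    config: RunConfig,
    seed: int,
    grids: dict | None = None,
) -> TopicResult:
    """Run folds, search, cutoff selection and explanation for one topic."""
    labels = [t.binary_label for t in triplets]
    y = encode_labels(labels)
    folds = make_folds(labels, k=config.k_folds, seed=seed, ids=[t.triplet_id for t in triplets])
    grids = grids if grids is not None else {
        fam: g for fam, g in default_grids().items() if fam in config.families
    }
    feature_config = config.feature_config()
    rfe_fraction = config.rfe_fraction if config.use_rfe else None
    if config.honest:
        best_config, oof, leaderboard = honest_search(
            triplets, labels, folds, feature_config,
            grids=grids, rfe_fraction=rfe_fraction, rfe_step=config.rfe_step, seed=seed,
        )
    else:
        matrix = assemble_features(triplets, feature_config)
        if rfe_fraction is not None:
            n_target = max(1, int(rfe_fraction * len(triplets)))
            if n_target < matrix.n_cols:
                selected = rfe_select(matrix, y, n_target=n_target, step=config.rfe_step, seed=seed)
                keep = [i for i, s in enumerate(matrix.specs)
                        if (s.family, s.name) in {(t.family, t.name) for t in selected}]
                matrix = dataclasses.replace(
                    matrix,
                    specs=[matrix.specs[i] for i in keep],
                    values=matrix.values[:, keep],
                )
        best_config, oof, leaderboard = model_search(matrix, y, folds, grids=grids, seed=seed)

    _, auc = evaluate_roc(oof, y)
    candidates = candidate_statistics(oof, y)
    baseline = float(np.mean(y == 0))
    chosen, feasible = select_cutoff(
        candidates, baseline,
        pos_precision_floor=config.pos_precision_floor, lam=config.cutoff_lambda,
    )
    report = utilization_report(y, oof, chosen.t)

    # full-data fit for the global explanation and the important-feature set
    matrix_all = assemble_features(triplets, feature_config)
    selected_specs = list(matrix_all.specs)
    if config.use_rfe and config.lexical == "tfidf":
        n_target = max(1, int(config.rfe_fraction * len(triplets)))
        if n_target < matrix_all.n_cols:
            selected_specs = rfe_select(
                matrix_all, y, n_target=n_target, step=config.rfe_step, seed=seed
            )
    explanation = None
    linear = ModelConfig(family="regularized-linear", seed=seed).make_estimator()
    linear.fit(matrix_all.values, y)
    explanation = coefficient_importance(
        linear, matrix_all.specs, top_k=config.top_k, model_id=topic
    )
    if config.lexical != "tfidf":
        selected_specs = explanation.top_specs()
    return TopicResult(
        topic=topic,
        triplets=triplets,
        labels=labels,
        folds=folds,
        best_config=best_config,
        oof=oof,
        leaderboard=leaderboard,
        auc=auc,
        cutoff_report=report,
        cutoff_feasible=feasible,
        selected_specs=selected_specs,
        explanation=explanation,
    )


def run_pipeline(config: RunConfig, grids: dict | None = None) -> dict[str, TopicResult]:
    """Execute the full pipeline and write every artifact to the run dir.

    Artifacts: the (possibly generated) corpus, the triplet table, per-topic
    out-of-fold predictions, the cutoff/utilization table, the partition
    summaries, the throughput table, explanation tables, and a log with
    versions, the seed and all resolved defaults.  Reruns with the same
    config are bit-identical for the deterministic stages.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "log.txt", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        import sklearn

        logger.info(
            "credfilter %s | python %s | numpy %s | sklearn %s | seed %d",
            __version__, platform.python_version(), np.__version__, sklearn.__version__,
            config.seed,
        )
        logger.info("resolved config: %s", dataclasses.asdict(config))
        (outdir / "run_config.json").write_text(
            json.dumps(dataclasses.asdict(config), indent=1, default=str), encoding="utf-8"
        )

        try:
            corpus, generated = _resolve_corpus(config)
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(f"stage corpus: {e}") from e
        if generated:
            write_corpus(corpus, outdir / "corpus.csv")

        all_triplets: list[Triplet] = []
        by_topic: dict[str, list[Triplet]] = {}
        for topic, articles in corpus.topics.items():
            trips: list[Triplet] = []
            for article in articles:
                trips.extend(build_triplets(article, remainder=config.remainder))
            labels = {t.binary_label for t in trips}
            if len(trips) < config.min_triplets or len(labels) < 2:
                logger.warning("skipping topic %s: %d triplets, classes %s",
                               topic, len(trips), sorted(labels))
                continue
            by_topic[topic] = trips
            all_triplets.extend(trips)
        if not by_topic:
            raise PipelineError("stage triplets: no topic has enough labelled triplets")
        write_triplets(all_triplets, outdir / "triplets.csv")

        results: dict[str, TopicResult] = {}
        oof_frames = []
        partition_frames = []
        for i, (topic, trips) in enumerate(sorted(by_topic.items())):
            seed_t = _topic_seed(config.seed, i)
            try:
                res = process_topic(topic, trips, config, seed_t, grids=grids)
            except Exception as e:
                raise PipelineError(f"stage train/cutoff (topic {topic}): {e}") from e
            results[topic] = res
            logger.info(
                "topic %s: n=%d k=%d best=%s f1-auc=%.3f cutoff=%.3f feasible=%s",
                topic, len(trips), res.folds.k, res.best_config.family, res.auc,
                res.cutoff_report.chosen_t, res.cutoff_feasible,
            )
            frame = res.oof.to_frame(res.labels)
            frame.insert(0, "topic", topic)
            oof_frames.append(frame)
            part = partition_summary(res.labels, res.oof, res.cutoff_report.chosen_t)
            part.insert(0, "topic", topic)
            partition_frames.append(part.reset_index(names="partition"))

        pd.concat(oof_frames).to_csv(outdir / "oof.csv", index=False)
        pd.concat(partition_frames).to_csv(outdir / "partition_summary.csv", index=False)
        util = utilization_table({t: r.cutoff_report for t, r in results.items()})
        util["auc"] = [results[t].auc for t in util["topic"]]
        util["feasible"] = [results[t].cutoff_feasible for t in util["topic"]]
        util.to_csv(outdir / "utilization.csv", index=False)

        # throughput economics from recorded annotation times
        try:
            times = time_summary(corpus)
            model = WorkdayModel()
            times["statements_per_day"] = [
                statements_per_day(m, model) for m in times["mean_s"]
            ]
            times["articles_per_day"] = [
                articles_per_day(s, model.statements_per_article)
                for s in times["statements_per_day"]
            ]
            times.to_csv(outdir / "throughput.csv")
        except ValueError:
            logger.warning("no annotation times; skipping throughput table")

        # explanation artifacts
        expl_rows = []
        for topic, res in results.items():
            if res.explanation is not None:
                df = res.explanation.to_frame()
                df.insert(0, "topic", topic)
                df["method"] = res.explanation.method
                expl_rows.append(df)
        if expl_rows:
            pd.concat(expl_rows).to_csv(outdir / "explanations.csv", index=False)
        shares = family_share_table({t: r.selected_specs for t, r in results.items()})
        shares.to_csv(outdir / "family_share.csv", index_label="topic")
        if len(results) >= 2:
            cross_topic_overlap(
                {t: r.selected_specs for t, r in results.items()}
            ).to_csv(outdir / "overlap.csv", index=False)
        logger.info("run complete: %d topics", len(results))
        return results
    finally:
        logger.removeHandler(handler)
        handler.close()
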