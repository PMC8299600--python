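"""Repeated-split validation protocol and full-pipeline orchestration.

The cohort is repeatedly split 60/40, stratified on the cluster labels
(round-half-up per stratum, matching a 126/136 cohort sending 76/82 patients
to training). Each trial retrains the stratifier from scratch with a
trial-derived seed, predicts the held-out patients, and records the log-rank
p-value between the predicted groups plus the AUC against the cluster labels.
The "optimal" model is the trial with the smallest test p-value. Reliability
resampling re-applies one trained model to random 60% subsamples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .cohort_io import Cohort, call_neoantigens
from .nn import ModelConfig
from .peptide_features import FeatureVocabulary, patient_feature_matrix, write_feature_matrix
from .stratifier import (
    HKMeansResult,
    TrainedModel,
    ZScaler,
    hkmeans_stratify,
    train_neodl,
    write_label_table,
)
from .survival_stats import (
    LogRankResult,
    SurvivalData,
    logrank_test,
    select_valid_features,
    write_screening_report,
)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; the message names the stage."""


@dataclass(frozen=True)
class TrialResult:
    trial: int
    seed: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    logrank_p: float
    auc: float
    accuracy: float
    significant: bool


@dataclass(frozen=True)
class PipelineConfig:
    alpha: float = 0.05
    k: int = 2
    split_ratio: float = 0.6
    n_trials: int = 300
    model: ModelConfig = field(default_factory=ModelConfig)
    master_seed: int = 20210723
    max_model_features: int | None = 189
    screen_engine: str = "newton"
    reliability_reps: int = 0
    reliability_fraction: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0, 1)")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @classmethod
    def desk_scale(cls, master_seed: int = 20210723, n_trials: int = 30,
                   epochs: int = 60) -> "PipelineConfig":
        """Scaled-down protocol for desk-size synthetic cohorts (n ~ 200).

        Thirty trials instead of 300, the stratifier consumes the 48
        strongest valid features instead of 189, and each trial model trains
        for 60 epochs instead of 1000 — sized so that trial models reach
        saturated, balanced predictions on planted two-group cohorts while a
        full validation run stays in the minutes range on one CPU.
        """
        return cls(n_trials=n_trials, master_seed=master_seed,
                   max_model_features=48,
                   model=ModelConfig(epochs=epochs, seed=master_seed))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(labels, ratio: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-stratum 60/40-style split; returns (train_idx, test_idx).

    Each stratum contributes round(ratio * size) members (round half up) to
    the training side, sampled without replacement.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be strictly inside (0, 1); a degenerate "
                         "split would leave one side empty")
    lab = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for value in np.unique(lab):
        idx = np.flatnonzero(lab == value)
        if idx.size < 2:
            raise ValueError(f"stratum {value!r} has fewer than 2 members")
        n_train = _round_half_up(ratio * idx.size)
        perm = rng.permutation(idx)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    if train.size == 0 or test.size == 0:
        raise ValueError("split left one side empty")
    return train, test


def _trial_seed(master_seed: int, trial: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(trial,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_split_trials(features: pd.DataFrame, scaler: ZScaler, labels,
                     survival: SurvivalData, config: PipelineConfig,
                     keep_models: bool = True):
    """Train/evaluate one model per stratified split trial.

    ``features`` are the raw (un-scaled) valid-feature columns indexed by
    patient; ``labels`` the binary cluster labels aligned to its rows.
    Returns (trials, models); models is empty when ``keep_models`` is False.
    """
    y = np.asarray(labels)
    ids = np.asarray(features.index)
    trials: list[TrialResult] = []
    models: list[TrainedModel | None] = []
    for i in range(config.n_trials):
        seed = _trial_seed(config.master_seed, i)
        train, test = stratified_split(y, config.split_ratio, seed)
        model_cfg = replace(config.model, seed=seed)
        z_train = scaler.transform(features.iloc[train])
        model = train_neodl(z_train, y[train], model_cfg, scaler)
        scores = model.predict_scores(features.iloc[test])
        pred = scores["predicted_label"].to_numpy()
        surv_test = survival.subset(test)
        if pred.min() == pred.max():
            warnings.warn(f"trial {i}: one predicted group is empty", stacklevel=2)
            p = 1.0
        else:
            p = logrank_test(surv_test.subset(pred == 1), surv_test.subset(pred == 0)).p
        if np.unique(y[test]).size > 1:
            auc = float(roc_auc_score(y[test], scores["probability"]))
        else:
            auc = float("nan")
        trials.append(TrialResult(
            trial=i, seed=seed,
            train_ids=tuple(ids[train]), test_ids=tuple(ids[test]),
            logrank_p=float(p), auc=auc,
            accuracy=float((pred == y[test]).mean()),
            significant=bool(p < 0.05),
        ))
        models.append(model if keep_models else None)
    return trials, models


def select_optimal_model(trials: Sequence[TrialResult],
                         models: Sequence[TrainedModel]):
    """The trial (and its model) with the smallest test log-rank p; ties go
    to the lowest trial index."""
    if not trials:
        raise ValueError("no trials to select from")
    best = min(range(len(trials)), key=lambda i: (trials[i].logrank_p, trials[i].trial))
    return trials[best], models[best]


def reliability_resampling(model: TrainedModel, features: pd.DataFrame,
                           survival: SurvivalData, fraction: float = 0.6,
                           reps: int = 300, seed: int = 0):
    """Apply a trained model to random subsamples; count significant splits.

    Returns (n_significant, p_values). ``fraction=1.0`` makes every rep the
    full cohort (all reps identical).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = features.shape[0]
    size = max(2, _round_half_up(fraction * n))
    ps = []
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=min(size, n), replace=False))
        scores = model.predict_scores(features.iloc[idx])
        pred = scores["predicted_label"].to_numpy()
        surv = survival.subset(idx)
        if pred.min() == pred.max():
            ps.append(1.0)
        else:
            ps.append(logrank_test(surv.subset(pred == 1), surv.subset(pred == 0)).p)
    ps_arr = np.asarray(ps)
    return int((ps_arr < 0.05).sum()), ps_arr


def apply_model(model: TrainedModel, features: pd.DataFrame,
                survival: SurvivalData):
    """External-cohort mode: score a second cohort and log-rank its groups.

    Returns (scores frame, LogRankResult); a one-group prediction yields
    p = 1 with a warning.
    """
    scores = model.predict_scores(features)
    pred = scores["predicted_label"].to_numpy()
    if pred.min() == pred.max():
        warnings.warn("external cohort: one predicted group is empty", stacklevel=2)
        return scores, LogRankResult(chi2=0.0, p=1.0)
    res = logrank_test(survival.subset(pred == 1), survival.subset(pred == 0))
    return scores, res


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    features: pd.DataFrame
    screening: pd.DataFrame
    valid_features: list[str]
    model_features: list[str]
    scaler: ZScaler
    clustering: HKMeansResult
    labels: np.ndarray            # binary, 1 = long-term
    survival: SurvivalData
    trials: list[TrialResult]
    best_trial: TrialResult
    best_model: TrainedModel
    auc_full: float
    reliability_significant: int | None = None


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def run_full_pipeline(cohort: Cohort, config: PipelineConfig,
                      vocab: FeatureVocabulary | None = None,
                      out_dir=None) -> PipelineResult:
    """featurize -> aggregate -> screen -> z-score -> hkmeans -> train -> validate."""
    with _stage("featurize"):
        called = call_neoantigens(cohort.pairs)
        if not called:
            raise ValueError("no called neoantigens in cohort "
                             f"{cohort.name!r} (nothing to featurize)")
        features = patient_feature_matrix(called, vocab)
        survival = SurvivalData.from_cohort(cohort, list(features.index))

    with _stage("screen"):
        valid, screening = select_valid_features(
            features, survival, alpha=config.alpha, engine=config.screen_engine)
        if not valid:
            raise ValueError("screening selected no valid features")
        model_features = valid
        if config.max_model_features and len(valid) > config.max_model_features:
            ranked = screening.loc[valid, "p"].sort_values(kind="stable")
            keep = set(ranked.index[:config.max_model_features])
            model_features = [f for f in valid if f in keep]

    with _stage("label"):
        scaler = ZScaler.fit(features[model_features])
        z = scaler.transform(features[model_features])
        clustering = hkmeans_stratify(z.to_numpy(), survival, k=config.k,
                                      seed=config.master_seed)
        labels = clustering.binary_labels()

    with _stage("validate"):
        trials, models = run_split_trials(features[model_features], scaler,
                                          labels, survival, config)
        best_trial, best_model = select_optimal_model(trials, models)
        scores_full = best_model.predict_scores(features[model_features])
        if np.unique(labels).size > 1:
            auc_full = float(roc_auc_score(labels, scores_full["probability"]))
        else:
            auc_full = float("nan")

    reliability = None
    if config.reliability_reps > 0:
        with _stage("reliability"):
            reliability, _ = reliability_resampling(
                best_model, features[model_features], survival,
                fraction=config.reliability_fraction,
                reps=config.reliability_reps, seed=config.master_seed)

    result = PipelineResult(
        features=features, screening=screening, valid_features=valid,
        model_features=model_features, scaler=scaler, clustering=clustering,
        labels=labels, survival=survival, trials=trials, best_trial=best_trial,
        best_model=best_model, auc_full=auc_full,
        reliability_significant=reliability,
    )
    if out_dir is not None:
        write_pipeline_artifacts(result, out_dir)
    return result


def write_trial_report(trials: Sequence[TrialResult], path) -> None:
    pd.DataFrame([
        {
            "trial": t.trial, "seed": t.seed, "n_train": len(t.train_ids),
            "n_test": len(t.test_ids), "logrank_p": t.logrank_p, "auc": t.auc,
            "accuracy": t.accuracy, "significant": int(t.significant),
        } for t in trials
    ]).to_csv(path, sep="\t", index=False)


def write_pipeline_artifacts(result: PipelineResult, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in {
        "features": "features.tsv", "screening": "screening.tsv",
        "labels": "labels.tsv", "trials": "trials.tsv",
        "model": "model.npz", "evaluation": "evaluation.json",
    }.items()}
    write_feature_matrix(result.features, paths["features"])
    write_screening_report(result.screening, paths["screening"])
    scores = result.best_model.predict_scores(result.features[result.model_features])
    write_label_table(paths["labels"], result.features.index,
                      result.clustering.labels, result.clustering.semantics,
                      probabilities=scores["probability"],
                      predicted=scores["predicted_label"])
    write_trial_report(result.trials, paths["trials"])
    result.best_model.save(paths["model"])
    summary = {
        "n_patients": int(result.features.shape[0]),
        "n_features": int(result.features.shape[1]),
        "n_valid_features": len(result.valid_features),
        "n_model_features": len(result.model_features),
        "cluster_sizes": {str(c): int((result.clustering.labels == c).sum())
                          for c in sorted(set(result.clustering.labels))},
        "n_trials": len(result.trials),
        "n_significant_trials": int(sum(t.significant for t in result.trials)),
        "best_trial": result.best_trial.trial,
        "best_trial_logrank_p": result.best_trial.logrank_p,
        "auc_full_cohort": result.auc_full,
        "reliability_significant": result.reliability_significant,
    }
    paths["evaluation"].write_text(json.dumps(summary, indent=2))
    return paths
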