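"""Task and postural-condition classification with leave-one-subject-out CV.

Two problems share one feature pipeline (covariance -> tangent vector):

* **Task classification** -- which of the six balance tasks a trial records.
  Tasks produce well-separated covariance structures, so a single multinomial
  logistic regression on tangent features suffices.
* **Condition classification** -- under which of three postural conditions
  (both feet down / one foot up / both feet up) the tasks were performed.
  Condition differences are nested inside much larger task differences, so
  one model per task is trained independently and a subject's session (their
  trials across tasks under one condition) is labeled by summing the member
  probability vectors and taking the argmax.

Evaluation is leave-one-subject-out: all models, including the tangent-space
reference points, are refitted per fold on the training subjects only.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from posturekit.datamodel_io import Dataset, Device, JointSubset, Trial
from posturekit.spd_geometry import (
    DEFAULT_SHRINKAGE,
    TangentFeatureModel,
    covariance_for_trial,
    logeuclidean_mean,
    tangent_project,
)

logger = logging.getLogger(__name__)


class TrainingError(ValueError):
    """The training set cannot support the requested fit."""


class PredictionError(ValueError):
    """A trial cannot be routed to a fitted model."""


@dataclass(frozen=True)
class TaskClassifier:
    """One tangent-feature model plus one multinomial logistic model."""

    feature_model: TangentFeatureModel
    logistic: LogisticRegression
    classes: tuple[int, ...]

    def predict_proba(self, covariances: Sequence[np.ndarray]) -> np.ndarray:
        feats = np.vstack(
            [tangent_project(c, self.feature_model) for c in covariances]
        )
        return self.logistic.predict_proba(feats)

    def predict(self, covariances: Sequence[np.ndarray]) -> np.ndarray:
        probs = self.predict_proba(covariances)
        return np.array(self.classes)[np.argmax(probs, axis=1)]


@dataclass(frozen=True)
class ConditionEnsemble:
    """Per-task condition classifiers combined by probability summation."""

    members: dict[int, TaskClassifier]
    conditions: tuple[int, ...]

    def __post_init__(self) -> None:
        for task_id, member in self.members.items():
            if set(member.classes) - set(self.conditions):
                raise TrainingError(
                    f"member for task {task_id} predicts classes outside "
                    f"{self.conditions}"
                )


@dataclass
class CVReport:
    """Cross-validation outcome: per-fold predictions and summaries.

    ``confusion`` has rows = true label, columns = predicted label, entries
    in percent of each row; ``accuracy_pct`` is the overall percent of
    prediction units (trials or sessions) labeled correctly.
    """

    target: str
    predictions: pd.DataFrame
    confusion: pd.DataFrame
    accuracy_pct: float
    n_folds: int
    fold_model_hashes: dict[str, str] = field(default_factory=dict)

    def per_class_accuracy(self) -> pd.Series:
        return pd.Series(np.diag(self.confusion), index=self.confusion.index)

    def to_json_dict(self) -> dict:
        return {
            "target": self.target,
            "accuracy_pct": self.accuracy_pct,
            "n_folds": self.n_folds,
            "confusion_percent": self.confusion.to_dict(),
            "predictions": self.predictions.to_dict(orient="records"),
        }


def _labels_and_covs(
    trials: Sequence[Trial],
    label_of,
    subset: JointSubset | None,
    shrinkage: float,
    cov_cache: dict | None = None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    labels = np.array([label_of(t) for t in trials])
    covs = []
    for t in trials:
        if cov_cache is not None and t.key in cov_cache:
            covs.append(cov_cache[t.key])
        else:
            c = covariance_for_trial(t, subset, shrinkage)
            if cov_cache is not None:
                cov_cache[t.key] = c
            covs.append(c)
    return labels, covs


def _fit_on_covariances(
    covs: Sequence[np.ndarray],
    labels: np.ndarray,
    subset: JointSubset | None,
    shrinkage: float,
    regularization: float,
) -> TaskClassifier:
    classes = tuple(sorted(set(int(y) for y in labels)))
    if len(classes) < 2:
        raise TrainingError(
            f"need at least 2 classes to fit, got {classes}"
        )
    reference = logeuclidean_mean(covs)
    fm = TangentFeatureModel.from_reference(reference, shrinkage, subset)
    feats = np.vstack([tangent_project(c, fm) for c in covs])
    # L2 penalty (sklearn default), strength C = regularization, lbfgs is
    # deterministic so refits on identical data reproduce identical weights
    logistic = LogisticRegression(
        C=regularization, solver="lbfgs", max_iter=2000
    )
    logistic.fit(feats, labels.astype(int))
    return TaskClassifier(feature_model=fm, logistic=logistic, classes=classes)


def fit_task_classifier(
    dataset: Dataset | Sequence[Trial],
    subset: JointSubset | None = JointSubset.UPPER_16,
    shrinkage: float = DEFAULT_SHRINKAGE,
    regularization: float = 1.0,
    device: Device | str = Device.MK2,
    _cov_cache: dict | None = None,
) -> TaskClassifier:
    """Fit the single-pipeline task classifier on every trial of one device.

    All trials are used regardless of the condition under which they were
    recorded; the multinomial logistic model is L2-penalized with strength
    ``regularization`` (scikit-learn's ``C``) and a deterministic solver.
    """
    trials = _device_trials(dataset, device)
    if subset is not None and Device(device) is Device.KFP:
        subset = None
    labels, covs = _labels_and_covs(
        trials, lambda t: t.task_id, subset, shrinkage, _cov_cache
    )
    return _fit_on_covariances(covs, labels, subset, shrinkage, regularization)


def fit_condition_ensemble(
    dataset: Dataset | Sequence[Trial],
    subset: JointSubset | None = JointSubset.UPPER_16,
    shrinkage: float = DEFAULT_SHRINKAGE,
    regularization: float = 1.0,
    device: Device | str = Device.MK2,
    _cov_cache: dict | None = None,
) -> ConditionEnsemble:
    """Fit one condition classifier per task, each on that task's trials only."""
    trials = _device_trials(dataset, device)
    if subset is not None and Device(device) is Device.KFP:
        subset = None
    tasks = sorted({t.task_id for t in trials})
    members: dict[int, TaskClassifier] = {}
    conditions: set[int] = set()
    for task_id in tasks:
        task_trials = [t for t in trials if t.task_id == task_id]
        labels, covs = _labels_and_covs(
            task_trials, lambda t: t.condition_id, subset, shrinkage,
            _cov_cache,
        )
        if len(set(labels.tolist())) < 2:
            raise TrainingError(
                f"task {task_id} has a single condition label; cannot fit "
                "its ensemble member"
            )
        members[task_id] = _fit_on_covariances(
            covs, labels, subset, shrinkage, regularization
        )
        conditions.update(members[task_id].classes)
    if len(members) < 6:
        warnings.warn(
            f"condition ensemble has {len(members)} members "
            f"(tasks {sorted(members)}); expected 6", stacklevel=2,
        )
    return ConditionEnsemble(members=members,
                             conditions=tuple(sorted(conditions)))


def predict_condition(
    ensemble: ConditionEnsemble,
    session: Sequence[Trial],
    subset: JointSubset | None = JointSubset.UPPER_16,
    shrinkage: float = DEFAULT_SHRINKAGE,
    _cov_cache: dict | None = None,
) -> tuple[int, np.ndarray]:
    """Label one session (a subject's trials under one condition).

    Each trial is routed to its own task's member; the member probability
    vectors are summed over the session and the condition with the highest
    sum wins.  Ties break toward the lowest condition index (logged).
    """
    if len(session) == 0:
        raise PredictionError("empty session")
    if session[0].device is Device.KFP:
        subset = None
    summed = np.zeros(len(ensemble.conditions))
    for trial in session:
        member = ensemble.members.get(trial.task_id)
        if member is None:
            raise PredictionError(
                f"no trained member for task {trial.task_id}"
            )
        if _cov_cache is not None and trial.key in _cov_cache:
            cov = _cov_cache[trial.key]
        else:
            cov = covariance_for_trial(trial, subset, shrinkage)
            if _cov_cache is not None:
                _cov_cache[trial.key] = cov
        probs = member.predict_proba([cov])[0]
        for cls, p in zip(member.classes, probs):
            summed[ensemble.conditions.index(cls)] += p
    best = int(np.argmax(summed))
    ties = np.flatnonzero(np.isclose(summed, summed[best], rtol=0, atol=1e-12))
    if ties.size > 1:
        logger.info(
            "probability-sum tie among conditions %s; breaking toward lowest",
            [ensemble.conditions[i] for i in ties],
        )
        best = int(ties[0])
    return ensemble.conditions[best], summed


def _device_trials(dataset: Dataset | Sequence[Trial],
                   device: Device | str) -> list[Trial]:
    device = Device(device)
    trials = [t for t in dataset if t.device is device]
    if not trials:
        raise TrainingError(f"no trials for device {device.value}")
    return trials


def _confusion_percent(true: np.ndarray, pred: np.ndarray,
                       classes: Sequence[int]) -> pd.DataFrame:
    classes = list(classes)
    counts = pd.DataFrame(0.0, index=classes, columns=classes)
    for t, p in zip(true, pred):
        counts.loc[t, p] += 1
    rows = counts.sum(axis=1).replace(0, np.nan)
    return counts.div(rows, axis=0) * 100.0


def _model_hash(models: Sequence[TaskClassifier]) -> str:
    h = hashlib.sha256()
    for m in models:
        h.update(np.ascontiguousarray(m.feature_model.reference).tobytes())
        h.update(np.ascontiguousarray(m.logistic.coef_).tobytes())
        h.update(np.ascontiguousarray(m.logistic.intercept_).tobytes())
    return h.hexdigest()


def loso_evaluate(
    dataset: Dataset | Sequence[Trial],
    target: Literal["task", "condition"] = "condition",
    subset: JointSubset | None = JointSubset.UPPER_16,
    shrinkage: float = DEFAULT_SHRINKAGE,
    regularization: float = 1.0,
    device: Device | str = Device.MK2,
    session_level: bool = True,
) -> CVReport:
    """Leave-one-subject-out evaluation of task or condition classification.

    Each subject is held out in turn; every model component, including the
    tangent reference, is refitted on the remaining subjects.  For the
    condition target the prediction unit is the session (probability
    summation across the held-out subject's task trials); set
    ``session_level=False`` for per-trial argmax predictions instead.
    """
    trials = _device_trials(dataset, device)
    if subset is not None and Device(device) is Device.KFP:
        subset = None
    subjects = sorted({t.subject_id for t in trials})
    if len(subjects) < 2:
        raise TrainingError("leave-one-subject-out needs at least 2 subjects")
    cov_cache: dict = {}
    records = []
    fold_hashes: dict[str, str] = {}
    for held in subjects:
        train = [t for t in trials if t.subject_id != held]
        test = [t for t in trials if t.subject_id == held]
        if target == "task":
            clf = fit_task_classifier(
                train, subset, shrinkage, regularization, device,
                _cov_cache=cov_cache,
            )
            fold_hashes[held] = _model_hash([clf])
            covs = [cov_cache.setdefault(
                t.key, covariance_for_trial(t, subset, shrinkage))
                for t in test]
            probs = clf.predict_proba(covs)
            for trial, p in zip(test, probs):
                pred = clf.classes[int(np.argmax(p))]
                records.append({
                    "subject": held, "unit": f"{held}/t{trial.task_id}"
                    f"/c{trial.condition_id}",
                    "true": trial.task_id, "predicted": int(pred),
                    "probabilities": p.tolist(),
                })
        elif target == "condition":
            ensemble = fit_condition_ensemble(
                train, subset, shrinkage, regularization, device,
                _cov_cache=cov_cache,
            )
            fold_hashes[held] = _model_hash(
                [ensemble.members[k] for k in sorted(ensemble.members)]
            )
            if session_level:
                for cond in sorted({t.condition_id for t in test}):
                    session = [t for t in test if t.condition_id == cond]
                    pred, summed = predict_condition(
                        ensemble, session, subset, shrinkage,
                        _cov_cache=cov_cache,
                    )
                    records.append({
                        "subject": held, "unit": f"{held}/c{cond}",
                        "true": cond, "predicted": int(pred),
                        "probabilities": summed.tolist(),
                    })
            else:
                for trial in test:
                    pred, summed = predict_condition(
                        ensemble, [trial], subset, shrinkage,
                        _cov_cache=cov_cache,
                    )
                    records.append({
                        "subject": held, "unit": f"{held}/t{trial.task_id}"
                        f"/c{trial.condition_id}",
                        "true": trial.condition_id, "predicted": int(pred),
                        "probabilities": summed.tolist(),
                    })
        else:
            raise ValueError(f"unknown target {target!r}")
    preds = pd.DataFrame.from_records(records)
    classes = sorted(set(preds["true"]) | set(preds["predicted"]))
    confusion = _confusion_percent(
        preds["true"].to_numpy(), preds["predicted"].to_numpy(), classes
    )
    accuracy = float((preds["true"] == preds["predicted"]).mean() * 100.0)
    return CVReport(
        target=target,
        predictions=preds,
        confusion=confusion,
        accuracy_pct=accuracy,
        n_folds=len(subjects),
        fold_model_hashes=fold_hashes,
    )


def learning_curve(
    dataset: Dataset | Sequence[Trial],
    train_sizes: Sequence[int],
    repeats: int = 10,
    seed: int = 0,
    subset: JointSubset | None = JointSubset.UPPER_16,
    shrinkage: float = DEFAULT_SHRINKAGE,
    regularization: float = 1.0,
    device: Device | str = Device.MK2,
) -> pd.DataFrame:
    """Condition-classification accuracy as training subjects increase.

    For each size, ``repeats`` random subject draws train the condition
    ensemble; all remaining subjects are evaluated session-level.  Returns a
    table of (train_size, mean_accuracy_pct, sd_accuracy_pct).
    """
    trials = _device_trials(dataset, device)
    if subset is not None and Device(device) is Device.KFP:
        subset = None
    subjects = sorted({t.subject_id for t in trials})
    train_sizes = list(train_sizes)
    if any(s < 1 or s > len(subjects) - 1 for s in train_sizes):
        raise ValueError(
            f"train sizes must be in [1, {len(subjects) - 1}]"
        )
    rng = np.random.default_rng(seed)
    cov_cache: dict = {}
    rows = []
    for size in train_sizes:
        accs = []
        for _ in range(repeats):
            picked = set(rng.choice(subjects, size=size, replace=False))
            train = [t for t in trials if t.subject_id in picked]
            test = [t for t in trials if t.subject_id not in picked]
            ensemble = fit_condition_ensemble(
                train, subset, shrinkage, regularization, device,
                _cov_cache=cov_cache,
            )
            correct = total = 0
            for subj in sorted({t.subject_id for t in test}):
                for cond in sorted({t.condition_id for t in test
                                    if t.subject_id == subj}):
                    session = [t for t in test if t.subject_id == subj
                               and t.condition_id == cond]
                    pred, _ = predict_condition(
                        ensemble, session, subset, shrinkage,
                        _cov_cache=cov_cache,
                    )
                    correct += int(pred == cond)
                    total += 1
            accs.append(100.0 * correct / total)
        rows.append({
            "train_size": size,
            "mean_accuracy_pct": float(np.mean(accs)),
            "sd_accuracy_pct": float(np.std(accs, ddof=1))
            if len(accs) > 1 else 0.0,
        })
    return pd.DataFrame(rows)
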