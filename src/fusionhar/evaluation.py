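"""Subject-specific and cross-subject (LOSO) evaluation protocols.

Both protocols share one hygiene rule: every fitted statistic — the
standardizer, the correlation-based selection and the classifier — is fitted
on training rows only and applied unchanged to the corresponding test rows.
Standardization and selection run on the full 75-column matrix of the
training partition; the scenario's signal filter is then applied to the
retained columns, so per-scenario feature sets are subsets of one selection
(as in a global selection followed by scenario projection).

Scores are the support-weighted F1 and the support-weighted one-vs-rest
ROC AUC; classes absent from a test set (or without negatives) are excluded
from the AUC average with a warning.  Cohort-level numbers are plain means
over subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._seeds import derive_seed
from .features import build_feature_matrix
from .modeling import ModelSpec, scenario_columns, train_model
from .preprocessing import extract_windows, upsample_record
from .selection import (
    DEFAULT_THRESHOLD,
    SelectionResult,
    StandardizationParams,
    apply_standardizer,
    correlation_select,
    fit_standardizer,
)
from .types import ACTIVITIES, SubjectRecord


@dataclass
class EvalResult:
    """Scores of one model on one scenario for one (held-out) subject."""

    subject_id: str
    scenario_id: int
    weighted_f1: float
    weighted_auc: float
    per_activity_f1: dict[str, float]
    confusion: list[list[int]]
    classes: list[str]
    n_features: int
    cv_fold_f1: list[float] | None = None
    cv_mean_f1: float | None = None

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "scenario_id": self.scenario_id,
            "weighted_f1": self.weighted_f1,
            "weighted_auc": self.weighted_auc,
            "per_activity_f1": self.per_activity_f1,
            "confusion": self.confusion,
            "classes": self.classes,
            "n_features": self.n_features,
            "cv_fold_f1": self.cv_fold_f1,
            "cv_mean_f1": self.cv_mean_f1,
        }


def weighted_scores(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    y_proba: np.ndarray,
    classes: list[str],
) -> dict:
    """Support-weighted F1 and one-vs-rest AUC, per-class F1, confusion.

    ``y_proba`` columns follow ``classes``.  Classes absent from ``y_true``
    (or present in every row, leaving no negatives) have undefined AUC and
    are excluded from the weighted AUC with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    y_proba = np.asarray(y_proba, dtype=np.float64)
    if not (len(y_true) == len(y_pred) == len(y_proba)):
        raise ValueError("y_true, y_pred and y_proba must have equal lengths")

    per_f1 = f1_score(y_true, y_pred, labels=classes, average=None, zero_division=0)
    support = np.array([(y_true == c).sum() for c in classes], dtype=float)
    wf1 = f1_score(y_true, y_pred, labels=classes, average="weighted", zero_division=0)

    aucs, auc_weights = [], []
    for k, c in enumerate(classes):
        pos = y_true == c
        if pos.sum() == 0 or pos.sum() == len(y_true):
            warnings.warn(
                f"class {c!r} has no {'positives' if pos.sum() == 0 else 'negatives'} "
                "in the test set; excluded from weighted AUC",
                stacklevel=2,
            )
            continue
        aucs.append(roc_auc_score(pos, y_proba[:, k]))
        auc_weights.append(support[k])
    wauc = float(np.average(aucs, weights=auc_weights)) if aucs else float("nan")

    conf = confusion_matrix(y_true, y_pred, labels=classes)
    return {
        "weighted_f1": float(wf1),
        "weighted_auc": wauc,
        "per_activity_f1": {c: float(f) for c, f in zip(classes, per_f1)},
        "confusion": conf,
    }


@dataclass
class FittedPipeline:
    """Standardizer + selection fitted on one training partition."""

    standardizer: StandardizationParams
    selection: SelectionResult


def fit_pipeline(train: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> FittedPipeline:
    """Fit standardization and correlation selection on training rows."""
    params = fit_standardizer(train)
    z = apply_standardizer(train, params)
    sel = correlation_select(z, labels=train["activity"].to_numpy(), threshold=threshold)
    return FittedPipeline(standardizer=params, selection=sel)


def _model_matrices(
    train: pd.DataFrame,
    test: pd.DataFrame,
    fp: FittedPipeline,
    scenario_id: int,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    cols = scenario_columns(scenario_id, fp.selection.retained)
    z_train = apply_standardizer(train, fp.standardizer)
    z_test = apply_standardizer(test, fp.standardizer)
    return z_train[cols].to_numpy(), z_test[cols].to_numpy(), cols


def subject_specific_eval(
    features: pd.DataFrame,
    scenario_id: int,
    model_spec: ModelSpec,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    cv_folds: int = 10,
) -> EvalResult:
    """Personal-model evaluation on one subject's feature matrix.

    Stratified 80/20 split (seeded); standardizer and selection are fitted
    on the 80 % only; stratified k-fold CV F1 (k up to ``cv_folds``, reduced
    with a warning when the smallest class is too small) is recorded on the
    training portion; the final model trains on the full training portion
    and is scored on the 20 % hold-out.
    """
    # canonical row order: results must not depend on how rows were stacked
    if "window_id" in features.columns:
        features = features.sort_values("window_id", kind="mergesort").reset_index(drop=True)
    y_all = features["activity"].to_numpy()
    classes = sorted(set(y_all))
    for c in classes:
        if (y_all == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 windows for this subject")

    train, test = train_test_split(
        features,
        test_size=0.2,
        stratify=y_all,
        random_state=derive_seed(seed, 10),
        shuffle=True,
    )
    fp = fit_pipeline(train, threshold=threshold)
    X_train, X_test, cols = _model_matrices(train, test, fp, scenario_id)
    y_train = train["activity"].to_numpy()
    y_test = test["activity"].to_numpy()

    # k-fold CV on the training portion (pipeline statistics fixed)
    min_class = min((y_train == c).sum() for c in classes)
    k = min(cv_folds, int(min_class))
    cv_scores: list[float] | None = None
    if k >= 2:
        if k < cv_folds:
            warnings.warn(
                f"reducing CV folds from {cv_folds} to {k} (smallest class has "
                f"{min_class} training windows)",
                stacklevel=2,
            )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=derive_seed(seed, 11))
        cv_scores = []
        for f, (tr_idx, va_idx) in enumerate(skf.split(X_train, y_train)):
            fold_spec = replace(model_spec, seed=derive_seed(model_spec.seed, 12, f))
            m = train_model(X_train[tr_idx], y_train[tr_idx], fold_spec)
            pred = m.predict(X_train[va_idx])
            cv_scores.append(
                float(
                    f1_score(
                        y_train[va_idx], pred, labels=classes,
                        average="weighted", zero_division=0,
                    )
                )
            )
    else:
        warnings.warn("smallest class too small for cross-validation; skipping CV", stacklevel=2)

    final_spec = replace(model_spec, seed=derive_seed(model_spec.seed, 13))
    model = train_model(X_train, y_train, final_spec)
    scores = weighted_scores(y_test, model.predict(X_test), model.predict_proba(X_test), classes)
    return EvalResult(
        subject_id=str(features["subject_id"].iloc[0]) if "subject_id" in features else "",
        scenario_id=scenario_id,
        weighted_f1=scores["weighted_f1"],
        weighted_auc=scores["weighted_auc"],
        per_activity_f1=scores["per_activity_f1"],
        confusion=scores["confusion"].tolist(),
        classes=classes,
        n_features=len(cols),
        cv_fold_f1=cv_scores,
        cv_mean_f1=float(np.mean(cv_scores)) if cv_scores else None,
    )


def cohort_mean(results: list[EvalResult]) -> dict:
    """Simple (unweighted) means over subjects."""
    classes = results[0].classes
    return {
        "weighted_f1": float(np.mean([r.weighted_f1 for r in results])),
        "weighted_auc": float(np.nanmean([r.weighted_auc for r in results])),
        "per_activity_f1": {
            c: float(np.mean([r.per_activity_f1[c] for r in results])) for c in classes
        },
    }


def subject_specific_cohort(
    features: pd.DataFrame,
    scenario_id: int,
    model_spec: ModelSpec,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    cv_folds: int = 10,
) -> tuple[list[EvalResult], dict]:
    """Run the personal-model protocol for every subject; report the mean."""
    results = []
    for i, sid in enumerate(sorted(features["subject_id"].unique())):
        sub = features[features["subject_id"] == sid]
        results.append(
            subject_specific_eval(
                sub, scenario_id, model_spec,
                seed=derive_seed(seed, 30, i), threshold=threshold, cv_folds=cv_folds,
            )
        )
    return results, cohort_mean(results)


def loso_eval(
    features: pd.DataFrame,
    scenario_id: int,
    model_spec: ModelSpec,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[list[EvalResult], dict]:
    """Leave-one-subject-out evaluation over a cohort feature matrix.

    ``features`` must carry a ``subject_id`` column.  For each held-out
    subject the standardizer, selection and model are fitted on the other
    subjects' windows only.
    """
    if "subject_id" not in features.columns:
        raise ValueError("LOSO requires a subject_id column")
    sort_cols = [c for c in ("subject_id", "window_id") if c in features.columns]
    features = features.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    subjects = sorted(features["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("LOSO requires at least 2 subjects")
    classes = sorted(set(features["activity"]))

    results = []
    for i, sid in enumerate(subjects):
        train = features[features["subject_id"] != sid]
        test = features[features["subject_id"] == sid]
        fp = fit_pipeline(train, threshold=threshold)
        X_train, X_test, cols = _model_matrices(train, test, fp, scenario_id)
        fold_spec = replace(model_spec, seed=derive_seed(model_spec.seed, 21, i))
        model = train_model(X_train, train["activity"].to_numpy(), fold_spec)
        scores = weighted_scores(
            test["activity"].to_numpy(),
            model.predict(X_test),
            model.predict_proba(X_test),
            classes,
        )
        results.append(
            EvalResult(
                subject_id=str(sid),
                scenario_id=scenario_id,
                weighted_f1=scores["weighted_f1"],
                weighted_auc=scores["weighted_auc"],
                per_activity_f1=scores["per_activity_f1"],
                confusion=scores["confusion"].tolist(),
                classes=classes,
                n_features=len(cols),
            )
        )
    return results, cohort_mean(results)


def cohort_feature_matrix(
    records: list[SubjectRecord],
    window_seconds: float = 7.0,
    allowed_activities: tuple[str, ...] = ACTIVITIES,
) -> pd.DataFrame:
    """Up-sample, window and featurize a cohort into one matrix."""
    frames = []
    for rec in records:
        ws = extract_windows(
            upsample_record(rec), window_seconds, allowed_activities=allowed_activities
        )
        frames.append(build_feature_matrix(ws, subject_id=rec.subject_id))
    return pd.concat(frames, ignore_index=True)


def window_size_sweep(
    records: list[SubjectRecord],
    sizes: list[float],
    scenario_ids: list[int],
    model_spec: ModelSpec,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> dict[tuple[float, int], float]:
    """Mean LOSO AUC for each (window size, scenario) combination.

    Sizes must lie in (0, 15] and give at least 8 samples on every channel.
    """
    upsampled = [upsample_record(r) for r in records]
    min_rate = 64.0
    for s in sizes:
        if not 0 < s <= 15:
            raise ValueError(f"window size {s} s outside (0, 15]")
        if round(s * min_rate) < 8:
            raise ValueError(f"window size {s} s yields fewer than 8 samples at {min_rate} Hz")
    out: dict[tuple[float, int], float] = {}
    for s in sizes:
        frames = [
            build_feature_matrix(extract_windows(rec, s), subject_id=rec.subject_id)
            for rec in upsampled
        ]
        feats = pd.concat(frames, ignore_index=True)
        for sc in scenario_ids:
            _, mean = loso_eval(feats, sc, model_spec, seed=seed, threshold=threshold)
            out[(s, sc)] = mean["weighted_auc"]
    return out
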