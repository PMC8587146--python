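"""Fusion scenarios, classifiers and impurity-based feature importance.

Seven early-fusion scenarios select which signals' feature columns enter
the model: single signals (1–3), pairs (4–6) and the full triple (7).
The headline classifier is a random forest with 300 trees of maximum depth
25; k-nearest-neighbours and multinomial logistic regression sit behind the
same interface for the model-choice comparison (their hyperparameters are
this package's defaults, k = 5 and unit-strength ridge).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier

from .signal_io import parse_feature_column

#: Scenario id → set of considered signals.
SCENARIOS: dict[int, tuple[str, ...]] = {
    1: ("ACC",),
    2: ("ECG",),
    3: ("PPG",),
    4: ("ACC", "ECG"),
    5: ("ACC", "PPG"),
    6: ("ECG", "PPG"),
    7: ("ACC", "ECG", "PPG"),
}

_SIGNAL_TAG = {"ACC-X": "ACC", "ACC-Y": "ACC", "ACC-Z": "ACC", "ECG": "ECG", "PPG": "PPG"}


def scenario_columns(scenario_id: int, columns: list[str]) -> list[str]:
    """The columns whose signal belongs to the scenario's signal set.

    The three accelerometer axes all map to the ``ACC`` tag.
    """
    if scenario_id not in SCENARIOS:
        raise ValueError(f"unknown scenario_id {scenario_id!r}; must be 1-7")
    wanted = set(SCENARIOS[scenario_id])
    out = []
    for col in columns:
        signal, _, _ = parse_feature_column(col)
        if _SIGNAL_TAG[signal] in wanted:
            out.append(col)
    return out


@dataclass
class ModelSpec:
    """Classifier family, hyperparameters and seed.

    Random-forest defaults (300 trees, depth 25) are the study settings;
    remaining forest hyperparameters are scikit-learn defaults.
    """

    family: str = "random_forest"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def build(self):
        if self.family == "random_forest":
            kw = {"n_estimators": 300, "max_depth": 25, "n_jobs": 1}
            kw.update(self.params)
            return RandomForestClassifier(random_state=self.seed, **kw)
        if self.family == "knn":
            kw = {"n_neighbors": 5}
            kw.update(self.params)
            return KNeighborsClassifier(**kw)
        if self.family == "multinomial_logistic":
            kw = {"C": 1.0, "max_iter": 2000}
            kw.update(self.params)
            return LogisticRegression(**kw)
        raise ValueError(f"unknown model family {self.family!r}")


def train_model(X: np.ndarray | pd.DataFrame, y: np.ndarray | pd.Series, spec: ModelSpec):
    """Fit a classifier exposing ``predict`` and ``predict_proba``."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if not np.all(np.isfinite(X)):
        raise ValueError("training matrix contains non-finite values")
    model = spec.build()
    model.fit(X, y)
    return model


@dataclass
class ImportanceRanking:
    """Features ranked by mean decrease in impurity, averaged over models."""

    entries: list[tuple[str, float]]  # (feature name, mean MDI), descending

    def top(self, k: int = 20) -> list[tuple[str, float]]:
        return self.entries[:k]

    def to_frame(self, k: int | None = None) -> pd.DataFrame:
        """Tabular report: rank, domain, signal, feature, score."""
        rows = []
        entries = self.entries if k is None else self.entries[:k]
        for rank, (name, score) in enumerate(entries, start=1):
            signal, domain, feature = parse_feature_column(name)
            rows.append(
                {"rank": rank, "domain": domain, "signal": signal,
                 "feature": feature, "score": score}
            )
        return pd.DataFrame(rows)


def importance_ranking(models: list, feature_names: list[str]) -> ImportanceRanking:
    """Average per-model MDI scores and rank features descending.

    All models must be random forests trained on the same feature set.
    """
    if not models:
        raise ValueError("importance_ranking requires at least one model")
    scores = []
    for m in models:
        if not hasattr(m, "feature_importances_"):
            raise ValueError("importance ranking requires random-forest models")
        imp = np.asarray(m.feature_importances_)
        if imp.shape != (len(feature_names),):
            raise ValueError(
                f"model has {imp.shape[0]} features, expected {len(feature_names)}"
            )
        scores.append(imp)
    mean_scores = np.mean(scores, axis=0)
    order = sorted(zip(feature_names, mean_scores), key=lambda e: (-e[1], e[0]))
    return ImportanceRanking(entries=[(n, float(s)) for n, s in order])
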