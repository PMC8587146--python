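"""Train-only standardization and correlation-based feature selection.

Standardization maps each feature column to ``z = (f - mu) / sigma`` with
``mu``/``sigma`` (population standard deviation) computed from training rows
only; degenerate columns (``sigma == 0``) map to all-zero.

Correlation-based feature selection (CFS) computes all pairwise Spearman
rank correlations on the training rows and, for every pair with
``|rho| > threshold`` (default 0.85), drops the member less correlated with
the target vector.  The target vector is the activity label coded as an
integer by the fixed alphabetical label → integer map; relevance is the
absolute Spearman correlation against that coding.  Qualifying pairs are
processed greedily from highest ``|rho|`` down (ties broken by column name),
skipping pairs with an already-dropped member; relevance ties drop the
lexicographically later name.  The result is deterministic and independent
of row order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .signal_io import feature_columns

DEFAULT_THRESHOLD = 0.85


@dataclass
class StandardizationParams:
    """Per-column training mean and population standard deviation."""

    mean: pd.Series
    std: pd.Series
    degenerate: list[str] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.mean)


@dataclass
class SelectionResult:
    """Retained columns (input order) and a log of dropped pairs."""

    retained: list[str]
    dropped: list[str]
    # (kept, dropped, |rho|, relevance_kept, relevance_dropped)
    log: list[tuple[str, str, float, float, float]] = field(default_factory=list)


def fit_standardizer(train: pd.DataFrame) -> StandardizationParams:
    """Compute per-column mu/sigma from training rows only."""
    cols = feature_columns(train)
    if len(train) < 2:
        raise ValueError("standardizer requires at least 2 training rows")
    X = train[cols].to_numpy(dtype=np.float64)
    mean = pd.Series(X.mean(axis=0), index=cols)
    std = pd.Series(X.std(axis=0), index=cols)  # population (ddof=0)
    degenerate = [c for c in cols if std[c] == 0.0]
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} constant feature column(s) flagged degenerate: "
            f"{degenerate[:5]}{'...' if len(degenerate) > 5 else ''}",
            stacklevel=2,
        )
    return StandardizationParams(mean=mean, std=std, degenerate=degenerate)


def apply_standardizer(matrix: pd.DataFrame, params: StandardizationParams) -> pd.DataFrame:
    """Apply training mu/sigma to a matrix (degenerate columns → 0)."""
    cols = feature_columns(matrix)
    if cols != list(params.mean.index):
        raise ValueError("matrix feature columns do not match standardizer parameters")
    out = matrix.copy()
    safe_std = params.std.replace(0.0, 1.0)
    z = (matrix[cols] - params.mean) / safe_std
    z[params.degenerate] = 0.0
    out[cols] = z
    return out


def label_codes(labels: pd.Series | np.ndarray) -> np.ndarray:
    """Integer-code labels by the fixed alphabetical map."""
    labels = np.asarray(labels)
    mapping = {lab: i for i, lab in enumerate(sorted(set(labels)))}
    return np.array([mapping[lab] for lab in labels], dtype=np.float64)


def correlation_select(
    train: pd.DataFrame,
    labels: pd.Series | np.ndarray | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> SelectionResult:
    """Drop one member of every feature pair with |Spearman| > threshold.

    ``labels`` defaults to the matrix's ``activity`` column.  Requires at
    least 3 training rows.
    """
    cols = feature_columns(train)
    if labels is None:
        if "activity" not in train.columns:
            raise ValueError("labels not given and matrix has no activity column")
        labels = train["activity"]
    labels = np.asarray(labels)
    if len(labels) != len(train):
        raise ValueError(f"labels length {len(labels)} != rows {len(train)}")
    if len(train) < 3:
        raise ValueError("correlation selection requires at least 3 rows")

    X = train[cols].to_numpy(dtype=np.float64)
    y = label_codes(labels)

    with warnings.catch_warnings():
        # constant columns yield undefined correlations; treated as 0 below
        warnings.simplefilter("ignore")
        if len(cols) == 1:
            rho = np.ones((1, 1))
        else:
            rho = stats.spearmanr(X).statistic
            if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
                rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        rel = np.array([stats.spearmanr(X[:, j], y).statistic for j in range(len(cols))])
    rho = np.nan_to_num(rho, nan=0.0)
    rel = np.abs(np.nan_to_num(rel, nan=0.0))

    pairs = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = abs(rho[i, j])
            if r > threshold:
                a, b = sorted((cols[i], cols[j]))
                pairs.append((r, a, b))
    # highest |rho| first; ties by lexicographic pair names
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))

    dropped: set[str] = set()
    log: list[tuple[str, str, float, float, float]] = []
    rel_of = dict(zip(cols, rel))
    changed = True
    while changed:
        changed = False
        for r, a, b in pairs:
            if a in dropped or b in dropped:
                continue
            ra, rb = rel_of[a], rel_of[b]
            if ra > rb:
                keep, drop = a, b
            elif rb > ra:
                keep, drop = b, a
            else:
                keep, drop = sorted((a, b))  # tie: drop the later name
            dropped.add(drop)
            log.append((keep, drop, float(r), float(rel_of[keep]), float(rel_of[drop])))
            changed = True

    retained = [c for c in cols if c not in dropped]
    return SelectionResult(retained=retained, dropped=sorted(dropped), log=log)


def selection_log_frame(result: SelectionResult) -> pd.DataFrame:
    """The dropped-pairs log as a DataFrame (for CSV export)."""
    return pd.DataFrame(
        result.log,
        columns=["kept", "dropped", "abs_rho", "relevance_kept", "relevance_dropped"],
    )
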