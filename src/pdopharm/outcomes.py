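"""Survival stratification and clinical concordance of PDO predictions.

Survival: Kaplan-Meier product-limit curves per signature group and the
two-group log-rank test (distant relapse-free survival is the intended
endpoint; any right-censored time-to-event cohort works).

Concordance: treatments are the unit of analysis.  A treatment counts as
a good clinical response when its RECIST outcome is CR, PR or SD, poor
when PD; the prediction is "effective" iff the regimen contains at least
one PDO-sensitive drug.  Reported metrics are accuracy, sensitivity,
specificity (on the 2x2 table), a rank-based AUC using the continuous
treatment score, percentile bootstrap CIs over treatment resamples
(default 1000 reps, 95%), and Pearson's chi-square without continuity
correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from sklearn.metrics import roc_auc_score

from .calls import TreatmentPrediction
from .io import GOOD_OUTCOMES, Outcome, SurvivalRecord, ValidationError

__all__ = [
    "KMEstimate",
    "ConfusionSummary",
    "km_fit",
    "logrank_test",
    "evaluate_concordance",
    "bootstrap_ci",
    "chi2_test",
    "preservation_fraction",
    "signature_similarity",
    "derivation_rate",
]

logger = logging.getLogger(__name__)


@dataclass
class KMEstimate:
    """Product-limit survival estimate for one group."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class ConfusionSummary:
    tp: int
    fn: int
    fp: int
    tn: int
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    auc: float | None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    chi2_p: float | None = None
    n_excluded_unknown: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def km_fit(records: Sequence[SurvivalRecord], group: str) -> KMEstimate:
    """Kaplan-Meier product-limit estimate for one group with right censoring."""
    sub = [r for r in records if r.group == group]
    if not sub:
        raise ValidationError(f"no records in group {group!r}")
    times = np.array([r.time for r in sub])
    events = np.array([r.event for r in sub], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_.iloc[:, 0]
    t = sf.index.values.astype(float)
    s = sf.values.astype(float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill().values
    return KMEstimate(group, t, s, at_risk)


def logrank_test(records: Sequence[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its p-value."""
    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {groups}")
    a = [r for r in records if r.group == groups[0]]
    b = [r for r in records if r.group == groups[1]]
    if not a or not b:
        raise ValidationError("both groups must be non-empty")
    if not any(r.event for r in records):
        raise ValidationError("need at least one observed event")
    res = _ll_logrank(
        [r.time for r in a], [r.time for r in b],
        event_observed_A=[r.event for r in a],
        event_observed_B=[r.event for r in b],
    )
    return float(res.test_statistic), float(res.p_value)


def _confusion(pred_good: np.ndarray, actual_good: np.ndarray
               ) -> tuple[int, int, int, int]:
    tp = int(np.sum(pred_good & actual_good))
    fn = int(np.sum(~pred_good & actual_good))
    fp = int(np.sum(pred_good & ~actual_good))
    tn = int(np.sum(~pred_good & ~actual_good))
    return tp, fn, fp, tn


def evaluate_concordance(predictions: Sequence[TreatmentPrediction],
                         bootstrap_reps: int = 1000,
                         ci_level: float = 0.95,
                         seed: int = 0) -> ConfusionSummary:
    """Concordance of treatment predictions with clinical outcomes.

    Positive class = good clinical response (CR/PR/SD); predicted positive
    = predicted_good.  Treatments with unknown outcomes are excluded with
    a logged count.  AUC ranks treatments by the continuous score.
    Sensitivity/specificity/AUC that are undefined on the data (an empty
    margin) are reported as None with a warning.
    """
    known = [p for p in predictions
             if p.treatment.outcome is not Outcome.UNKNOWN]
    n_excl = len(predictions) - len(known)
    if n_excl:
        logger.info("excluded %d treatment(s) with unknown outcome", n_excl)
    if not known:
        raise ValidationError("no treatment has a known outcome")
    pred = np.array([p.predicted_good for p in known], dtype=bool)
    actual = np.array([p.treatment.outcome in GOOD_OUTCOMES for p in known],
                      dtype=bool)
    score = np.array([p.score for p in known], dtype=float)

    tp, fn, fp, tn = _confusion(pred, actual)
    summary = ConfusionSummary(
        tp, fn, fp, tn,
        accuracy=(tp + tn) / len(known),
        sensitivity=_safe_ratio(tp, tp + fn, "sensitivity"),
        specificity=_safe_ratio(tn, tn + fp, "specificity"),
        auc=_safe_auc(actual, score),
        n_excluded_unknown=n_excl,
    )

    data = np.column_stack([pred, actual, score])
    metric_fns: dict[str, Callable[[np.ndarray], float]] = {
        "accuracy": lambda d: float(np.mean(d[:, 0] == d[:, 1])),
        "sensitivity": lambda d: _nan_ratio(
            np.sum((d[:, 0] == 1) & (d[:, 1] == 1)), np.sum(d[:, 1] == 1)),
        "specificity": lambda d: _nan_ratio(
            np.sum((d[:, 0] == 0) & (d[:, 1] == 0)), np.sum(d[:, 1] == 0)),
        "auc": lambda d: _safe_auc(d[:, 1].astype(bool), d[:, 2], warn=False,
                                   as_nan=True),
    }
    for name, fn_ in metric_fns.items():
        if getattr(summary, name) is None:
            continue
        summary.ci[name] = bootstrap_ci(fn_, data, reps=bootstrap_reps,
                                        level=ci_level, seed=seed)

    if min(tp + fn, tn + fp, tp + fp, fn + tn) > 0:
        _, summary.chi2_p = chi2_test(np.array([[tp, fn], [fp, tn]]))
    else:
        warnings.warn("degenerate 2x2 margin: chi-square not computed",
                      stacklevel=2)
    return summary


def _safe_ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined (empty margin); reported as missing",
                      stacklevel=3)
        return None
    return num / den


def _nan_ratio(num, den) -> float:
    return float(num / den) if den > 0 else float("nan")


def _safe_auc(actual: np.ndarray, score: np.ndarray, warn: bool = True,
              as_nan: bool = False):
    if len(np.unique(actual)) < 2:
        if warn:
            warnings.warn("AUC undefined (single outcome class)", stacklevel=3)
        return float("nan") if as_nan else None
    return float(roc_auc_score(actual, score))


def bootstrap_ci(metric: Callable[[np.ndarray], float], data: np.ndarray,
                 reps: int = 1000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap CI of ``metric`` over row resamples of ``data``.

    Resampling is with replacement at the row (treatment) level; the
    interval endpoints are empirical quantiles of the ``reps`` resampled
    metric values (NaN replicates from degenerate resamples are dropped).
    Deterministic for a fixed seed.
    """
    data = np.asarray(data)
    n = data.shape[0]
    if n == 0:
        raise ValidationError("empty data")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    vals = np.empty(reps)
    for i in range(reps):
        idx = rng.integers(0, n, size=n)
        vals[i] = metric(data[idx])
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValidationError("metric undefined on every bootstrap resample")
    alpha = (1.0 - level) / 2.0
    # endpoints are exact order statistics of the resampled metric
    lo = np.quantile(vals, alpha, method="lower")
    hi = np.quantile(vals, 1.0 - alpha, method="higher")
    return float(lo), float(hi)


def chi2_test(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction, 1 df."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValidationError(f"need a 2x2 table, got shape {table.shape}")
    if (table < 0).any():
        raise ValidationError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("zero margin in 2x2 table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def preservation_fraction(parent: Iterable, organoid: Iterable) -> float:
    """Percent of the parent-tumor gene set retained in the organoid:
    100 * |parent & organoid| / |parent|."""
    parent, organoid = set(parent), set(organoid)
    if not parent:
        raise ValidationError("parent gene set is empty")
    return 100.0 * len(parent & organoid) / len(parent)


def signature_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """Cosine similarity between two non-negative contribution vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("contribution vectors must be non-negative")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("zero vector")
    return float(a @ b / (na * nb))


def derivation_rate(successes: int, attempts: int) -> float:
    """Success percentage of a derivation count, e.g. organoid lines
    established per tissue sample: 100 * successes / attempts."""
    if attempts <= 0:
        raise ValidationError("attempts must be positive")
    if not 0 <= successes <= attempts:
        raise ValidationError("successes must be in [0, attempts]")
    return 100.0 * successes / attempts
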