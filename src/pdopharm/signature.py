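"""Pharmaco-transcriptomic signature of microtubule-drug sensitivity.

The signature is derived from bulk expression of the organoid lines and
their IC50s for the six microtubule-targeting drugs (docetaxel,
paclitaxel, vinorelbine, ixabepilone, vincristine, vinblastine):

1. counts -> log2(CPM + 1);
2. differential expression between pan-sensitive and pan-resistant lines
   (Welch two-sample t on log2 expression, Benjamini-Hochberg q-values),
   filtered at q <= 0.01 and |log2 fold change| >= 1 (i.e. FC >= 2);
3. Spearman correlation of each surviving gene against the per-line
   median log10 IC50 across the six drugs; genes are kept when
   |rho| > 0.3 and the correlation sign is consistent with the DE
   direction (genes up in sensitive lines must anticorrelate with IC50).

The signature supports (a) hierarchical clustering of lines into a
sensitive-like and a non-sensitive class (average linkage on
1 - Pearson correlation) and (b) a linear max-margin classifier
(hinge loss + L2, deterministic full-batch subgradient descent on
standardized features) for labelling external expression profiles.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClassifierMixin
from statsmodels.stats.multitest import multipletests

from .io import MICROTUBULE_DRUGS, ValidationError

__all__ = [
    "Direction",
    "SignatureGene",
    "normalize_counts",
    "differential_expression",
    "spearman_filter",
    "SignatureSelector",
    "cluster_pdos",
    "HingeLinearClassifier",
    "train_classifier",
    "apply_classifier",
]

logger = logging.getLogger(__name__)


class Direction(str, enum.Enum):
    UP_IN_SENSITIVE = "up_in_sensitive"
    DOWN_IN_SENSITIVE = "down_in_sensitive"


@dataclass(frozen=True)
class SignatureGene:
    gene_id: str
    direction: Direction
    log2fc: float
    fdr_q: float
    rho: float


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) on a genes x samples integer count matrix."""
    if counts.shape[1] < 2:
        raise ValidationError("need >= 2 samples")
    if (counts.values < 0).any():
        raise ValidationError("counts must be non-negative")
    libs = counts.sum(axis=0)
    zero = libs[libs == 0]
    if len(zero):
        raise ValidationError(f"all-zero sample(s): {list(zero.index)}")
    cpm = counts / libs * 1e6
    return np.log2(cpm + 1.0)


def differential_expression(expr: pd.DataFrame, groups: pd.Series
                            ) -> pd.DataFrame:
    """Welch two-sample t per gene on log2 expression, BH-adjusted.

    ``groups`` maps sample -> {'pan_sensitive', 'pan_resistant'};
    log2fc is mean(sensitive) - mean(resistant), so positive values are
    up in the sensitive lines.  Returns a genes-indexed frame with
    columns log2fc, p, q.
    """
    groups = groups.reindex(expr.columns)
    sens = expr.loc[:, groups == "pan_sensitive"].values
    res = expr.loc[:, groups == "pan_resistant"].values
    if sens.shape[1] < 3 or res.shape[1] < 3:
        raise ValidationError(
            f"need >= 3 samples per group, got {sens.shape[1]} sensitive"
            f" and {res.shape[1]} resistant")
    log2fc = sens.mean(axis=1) - res.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(sens, res, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    _, q, *_ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"log2fc": log2fc, "p": p, "q": q}, index=expr.index)


def spearman_filter(de: pd.DataFrame, expr: pd.DataFrame,
                    mt_ic50: pd.DataFrame, rho_min: float = 0.3,
                    de_fdr_max: float = 0.01, de_fc_min: float = 2.0,
                    aggregate: str = "median") -> list[SignatureGene]:
    """Filter DE hits into the drug-sensitive response signature.

    ``mt_ic50`` is a PDO x drug table of IC50s (molar) for the six
    microtubule drugs.  Each gene's expression is rank-correlated
    (Spearman, tie-corrected average ranks) against the per-PDO summary
    of log10 IC50 (``aggregate``: 'median' over the six drugs, or 'mean'
    of the per-drug correlations when 'per_drug').  A gene enters the
    signature iff it passes the DE thresholds, |rho| > rho_min and the
    correlation sign opposes its DE direction (high expression of an
    up-in-sensitive gene must track low IC50).
    """
    samples = [s for s in expr.columns if s in mt_ic50.index]
    if len(samples) < 5:
        raise ValidationError(
            f"need >= 5 samples with both expression and IC50s, got {len(samples)}")
    drugs = [d for d in MICROTUBULE_DRUGS if d in mt_ic50.columns]
    if not drugs:
        raise ValidationError("no microtubule-drug columns in the IC50 table")
    log_ic50 = np.log10(mt_ic50.loc[samples, drugs])

    fc_min_log2 = np.log2(de_fc_min)
    hits = de[(de["q"] <= de_fdr_max) & (de["log2fc"].abs() >= fc_min_log2)]

    out: list[SignatureGene] = []
    summary = log_ic50.median(axis=1).values
    for gene, row in hits.iterrows():
        x = expr.loc[gene, samples].values.astype(float)
        if aggregate == "median":
            rho = _spearman(x, summary)
        elif aggregate == "per_drug":
            rho = float(np.mean([_spearman(x, log_ic50[d].values)
                                 for d in drugs]))
        else:
            raise ValueError(f"unknown aggregate {aggregate!r}")
        if not np.isfinite(rho) or abs(rho) <= rho_min:
            continue
        direction = (Direction.UP_IN_SENSITIVE if row["log2fc"] > 0
                     else Direction.DOWN_IN_SENSITIVE)
        # sign consistency: up-in-sensitive genes must anticorrelate with IC50
        if direction is Direction.UP_IN_SENSITIVE and rho >= 0:
            continue
        if direction is Direction.DOWN_IN_SENSITIVE and rho <= 0:
            continue
        out.append(SignatureGene(str(gene), direction, float(row["log2fc"]),
                                 float(row["q"]), rho))
    logger.info("signature: %d of %d DE hits pass the correlation filter",
                len(out), len(hits))
    return out


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


class SignatureSelector(BaseEstimator):
    """sklearn-style wrapper: fit derives the signature, transform subsets.

    ``fit(X, y, mt_ic50=...)`` takes X as samples x genes log expression,
    y as the pan_sensitive / pan_resistant group labels (samples without a
    group are ignored for the DE step but used for correlation when they
    carry IC50s).  After fitting, ``signature_`` holds the SignatureGene
    list and ``gene_ids_`` the selected columns; ``transform`` restricts a
    samples x genes matrix to the signature.
    """

    def __init__(self, de_fdr_max: float = 0.01, de_fc_min: float = 2.0,
                 rho_min: float = 0.3, aggregate: str = "median"):
        self.de_fdr_max = de_fdr_max
        self.de_fc_min = de_fc_min
        self.rho_min = rho_min
        self.aggregate = aggregate

    def fit(self, X: pd.DataFrame, y: pd.Series, mt_ic50: pd.DataFrame
            ) -> "SignatureSelector":
        expr = X.T  # internal convention: genes x samples
        groups = y.reindex(X.index)
        de = differential_expression(
            expr.loc[:, groups.isin(["pan_sensitive", "pan_resistant"])],
            groups)
        self.de_ = de
        self.signature_ = spearman_filter(
            de, expr, mt_ic50, rho_min=self.rho_min,
            de_fdr_max=self.de_fdr_max, de_fc_min=self.de_fc_min,
            aggregate=self.aggregate)
        self.gene_ids_ = [g.gene_id for g in self.signature_]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[:, self.gene_ids_]

    def signature_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.gene_id, g.direction.value, g.log2fc, g.fdr_q, g.rho)
             for g in self.signature_],
            columns=["gene_id", "direction", "log2fc", "fdr_q", "rho"])


def cluster_pdos(expr_sig: pd.DataFrame,
                 signature: Sequence[SignatureGene]) -> pd.Series:
    """Split lines into sensitive-like vs non-sensitive classes.

    ``expr_sig`` is samples x signature-genes log expression.  Average-
    linkage agglomeration on 1 - Pearson correlation between sample
    profiles, cut at two clusters; the cluster with the higher mean
    expression of up-in-sensitive genes (minus down genes) is labelled
    ``sensitive_class``, the other ``non_sensitive``.
    """
    if expr_sig.shape[0] < 2:
        raise ValidationError("need >= 2 samples to cluster")
    if expr_sig.shape[1] < 2:
        raise ValidationError("need >= 2 signature genes to cluster")
    X = expr_sig.values.astype(float)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        raise ValidationError("constant expression profile(s): degenerate"
                              " correlation distance")
    corr = np.corrcoef(X)
    dist = 1.0 - corr
    iu = np.triu_indices_from(dist, k=1)
    Z = linkage(np.maximum(dist[iu], 0.0), method="average")
    assign = fcluster(Z, t=2, criterion="maxclust")

    up = np.array([g.direction is Direction.UP_IN_SENSITIVE
                   for g in signature if g.gene_id in expr_sig.columns])
    cols = [g.gene_id for g in signature if g.gene_id in expr_sig.columns]
    score_per_sample = (expr_sig[cols].values * np.where(up, 1.0, -1.0)).mean(axis=1)
    means = {c: score_per_sample[assign == c].mean() for c in np.unique(assign)}
    sensitive_cluster = max(means, key=means.get)
    labels = np.where(assign == sensitive_cluster, "sensitive_class",
                      "non_sensitive")
    return pd.Series(labels, index=expr_sig.index, name="group")


class HingeLinearClassifier(BaseEstimator, ClassifierMixin):
    """Linear max-margin classifier: hinge loss + L2, full-batch subgradient.

    Deterministic training: features are standardized with the training
    mean/sd, weights start at zero and follow ``n_epochs`` full-batch
    subgradient steps with the 1/(lambda * t) schedule.  Binary labels
    are mapped to +/-1 in sorted order (``classes_[1]`` is the positive
    decision side).  Missing features at prediction time are imputed at
    the training mean (equivalently: zero after standardization).
    """

    def __init__(self, reg_lambda: float = 0.01, n_epochs: int = 500,
                 random_state: int = 0):
        self.reg_lambda = reg_lambda
        self.n_epochs = n_epochs
        self.random_state = random_state

    def fit(self, X, y) -> "HingeLinearClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValidationError(
                f"need exactly 2 classes, got {list(self.classes_)}")
        t = np.where(y == self.classes_[1], 1.0, -1.0)
        self.center_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Z = (X - self.center_) / self.scale_
        n, p = Z.shape
        w = np.zeros(p)
        b = 0.0
        lam = self.reg_lambda
        for step in range(1, self.n_epochs + 1):
            margin = t * (Z @ w + b)
            active = margin < 1.0
            grad_w = lam * w - (t[active, None] * Z[active]).sum(axis=0) / n
            grad_b = -t[active].sum() / n
            eta = 1.0 / (lam * step)
            w -= eta * grad_w
            b -= eta * grad_b
        self.coef_ = w
        self.intercept_ = float(b)
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = (X - self.center_) / self.scale_
        return Z @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        return np.where(d >= 0, self.classes_[1], self.classes_[0])


def train_classifier(expr_sig: pd.DataFrame, labels: pd.Series,
                     reg_lambda: float = 0.01, n_epochs: int = 500,
                     random_state: int = 0) -> HingeLinearClassifier:
    """Train the signature classifier on samples x signature-genes data."""
    labels = labels.reindex(expr_sig.index)
    clf = HingeLinearClassifier(reg_lambda, n_epochs, random_state)
    clf.fit(expr_sig.values, labels.values)
    clf.feature_names_ = list(expr_sig.columns)
    return clf


def apply_classifier(model: HingeLinearClassifier,
                     new_expr: pd.DataFrame) -> pd.Series:
    """Label external samples; missing signature genes are imputed at the
    training mean (logged)."""
    cols = model.feature_names_
    missing = [c for c in cols if c not in new_expr.columns]
    if missing:
        logger.info("imputing %d missing signature gene(s) at training mean",
                    len(missing))
    X = np.empty((new_expr.shape[0], len(cols)))
    for j, c in enumerate(cols):
        if c in new_expr.columns:
            X[:, j] = new_expr[c].values
        else:
            X[:, j] = model.center_[j]
    return pd.Series(model.predict(X), index=new_expr.index, name="predicted")
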