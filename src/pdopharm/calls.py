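"""Tertile drug-response calls and treatment-level predictions.

Per drug, PDOs are ranked by IC50 and split into three equal-rank groups:
sensitive (lowest third), moderate (middle third), resistant (top third),
with cutoffs at ranks ceil(n/3) and ceil(2n/3).  The split is rank-based,
so any strictly monotone transform of the IC50s yields identical calls.

Bound rule: when more than a tertile of the cohort is censored at the top
of the tested range, all of those PDOs are called resistant and the rest
are split into two equal-rank halves (sensitive / moderate); symmetrically
for censoring at the bottom of the range (all censored PDOs sensitive,
rest split moderate / resistant).  If both censored fractions exceed the
tertile fraction the drug is ambiguous and an error is raised.

A treatment is predicted effective iff its regimen contains at least one
drug called sensitive for the matching PDO (optionally: sensitive or
moderate).  The continuous treatment score counts sensitive drugs fully
and moderate drugs half, per called drug.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dose_response import Censor, IC50Record
from .io import TreatmentRecord

__all__ = [
    "Label",
    "Basis",
    "ResponseCall",
    "TreatmentPrediction",
    "InsufficientCohortError",
    "AmbiguousBoundRuleError",
    "UntestableTreatmentError",
    "TertileResponseClassifier",
    "classify_drug",
    "call_matrix",
    "predict_treatment",
]

logger = logging.getLogger(__name__)


class Label(str, enum.Enum):
    SENSITIVE = "sensitive"
    MODERATE = "moderate"
    RESISTANT = "resistant"


#: ordering used for "best call in regimen" (lower is better)
_LABEL_ORDER = {Label.SENSITIVE: 0, Label.MODERATE: 1, Label.RESISTANT: 2}


class Basis(str, enum.Enum):
    TERTILE = "tertile"
    BOUND_RULE = "bound_rule"


class InsufficientCohortError(ValueError):
    """Fewer than three PDOs carry an IC50 for the drug."""


class AmbiguousBoundRuleError(ValueError):
    """Both range bounds hold more than a tertile of the censored mass."""


class UntestableTreatmentError(ValueError):
    """No drug of the regimen has a response call."""


@dataclass(frozen=True)
class ResponseCall:
    pdo_id: str
    drug_id: str
    label: Label
    basis: Basis


@dataclass(frozen=True)
class TreatmentPrediction:
    treatment: TreatmentRecord
    best_call: Label
    predicted_good: bool
    score: float
    n_called: int


def _rank_blocks(values: np.ndarray, cut_fracs: Sequence[float]) -> np.ndarray:
    """Assign block indices 0..len(cut_fracs) by ascending rank with cutoffs
    at ceil(n * f); tied values all inherit the block of their lowest rank."""
    n = values.size
    order = np.argsort(values, kind="stable")
    cuts = [int(np.ceil(n * f)) for f in cut_fracs]
    block_of_rank = np.zeros(n, dtype=int)
    for c in cuts:
        block_of_rank[c:] += 1
    blocks = np.empty(n, dtype=int)
    blocks[order] = block_of_rank
    # ties share the block of the lowest-ranked member
    sorted_vals = values[order]
    sorted_blocks = block_of_rank.copy()
    for i in range(1, n):
        if sorted_vals[i] == sorted_vals[i - 1]:
            sorted_blocks[i] = sorted_blocks[i - 1]
    blocks[order] = sorted_blocks
    return blocks


class TertileResponseClassifier(BaseEstimator):
    """Per-drug tertile classifier over a cohort of IC50 records.

    ``fit`` ranks the cohort and stores the per-PDO labels in ``labels_``
    and the decision path in ``basis_``; ``fit_predict`` returns the labels.
    The classification is transductive: labels apply to the fitted cohort.
    """

    def __init__(self, tertile_fraction: float = 1.0 / 3.0):
        self.tertile_fraction = tertile_fraction

    def fit(self, records: Sequence[IC50Record]) -> "TertileResponseClassifier":
        records = list(records)
        n = len(records)
        if n < 3:
            raise InsufficientCohortError(
                f"need >= 3 PDOs with an IC50, got {n}")
        drugs = {r.drug_id for r in records}
        if len(drugs) > 1:
            raise ValueError(f"records span multiple drugs: {sorted(drugs)}")
        ic50 = np.array([r.ic50 for r in records], dtype=float)
        at_max = np.array([r.censor is Censor.AT_MAX for r in records])
        at_min = np.array([r.censor is Censor.AT_MIN for r in records])
        frac_max = at_max.mean()
        frac_min = at_min.mean()
        f = self.tertile_fraction

        labels = np.empty(n, dtype=object)
        if frac_max > f and frac_min > f:
            raise AmbiguousBoundRuleError(
                f"both censored fractions exceed {f:.3f}"
                f" (at_max {frac_max:.3f}, at_min {frac_min:.3f})")
        if frac_max > f:
            self.basis_ = Basis.BOUND_RULE
            labels[at_max] = Label.RESISTANT
            rest = ~at_max
            if rest.any():
                halves = _rank_blocks(ic50[rest], [0.5])
                labels[np.flatnonzero(rest)[halves == 0]] = Label.SENSITIVE
                labels[np.flatnonzero(rest)[halves == 1]] = Label.MODERATE
        elif frac_min > f:
            self.basis_ = Basis.BOUND_RULE
            labels[at_min] = Label.SENSITIVE
            rest = ~at_min
            if rest.any():
                halves = _rank_blocks(ic50[rest], [0.5])
                labels[np.flatnonzero(rest)[halves == 0]] = Label.MODERATE
                labels[np.flatnonzero(rest)[halves == 1]] = Label.RESISTANT
        else:
            self.basis_ = Basis.TERTILE
            blocks = _rank_blocks(ic50, [f, 2 * f])
            for b, lab in enumerate((Label.SENSITIVE, Label.MODERATE,
                                     Label.RESISTANT)):
                labels[blocks == b] = lab
        self.labels_ = labels
        self.records_ = records
        return self

    def fit_predict(self, records: Sequence[IC50Record]) -> np.ndarray:
        return self.fit(records).labels_


def classify_drug(records: Sequence[IC50Record],
                  tertile_fraction: float = 1.0 / 3.0) -> list[ResponseCall]:
    """Tertile calls for one drug across the cohort (see module docstring)."""
    clf = TertileResponseClassifier(tertile_fraction).fit(records)
    return [
        ResponseCall(r.pdo_id, r.drug_id, lab, clf.basis_)
        for r, lab in zip(clf.records_, clf.labels_)
    ]


def call_matrix(ic50_table: pd.DataFrame,
                tertile_fraction: float = 1.0 / 3.0
                ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Apply classify_drug per drug of a long IC50 table.

    ``ic50_table`` needs columns pdo_id, drug_id, ic50_molar, censor.
    Returns a long calls table (pdo_id, drug_id, label, basis) plus a dict
    of per-drug errors (classification continues past failing drugs).
    """
    if ic50_table.empty:
        warnings.warn("empty IC50 table: no calls produced", stacklevel=2)
        return (pd.DataFrame(columns=["pdo_id", "drug_id", "label", "basis"]),
                {})
    rows, errors = [], {}
    for drug, sub in ic50_table.groupby("drug_id", sort=True):
        records = [
            IC50Record(str(r.pdo_id), str(drug), float(r.ic50_molar),
                       Censor(r.censor))
            for r in sub.itertuples(index=False)
        ]
        try:
            calls = classify_drug(records, tertile_fraction)
        except (InsufficientCohortError, AmbiguousBoundRuleError) as exc:
            errors[str(drug)] = str(exc)
            logger.warning("drug %s not classified: %s", drug, exc)
            continue
        rows += [(c.pdo_id, c.drug_id, c.label.value, c.basis.value)
                 for c in calls]
    df = pd.DataFrame(rows, columns=["pdo_id", "drug_id", "label", "basis"])
    for drug, sub in df.groupby("drug_id"):
        counts = sub["label"].value_counts().to_dict()
        logger.info("calls for %s: %s", drug, counts)
    return df, errors


def predict_treatment(treatment: TreatmentRecord,
                      calls: Mapping[tuple[str, str], Label] | pd.DataFrame,
                      moderate_counts_as_good: bool = False
                      ) -> TreatmentPrediction:
    """Roll per-drug calls up to a treatment-level prediction.

    best_call is the best label among the regimen's called drugs
    (sensitive > moderate > resistant); predicted_good is True iff
    best_call is sensitive (or moderate too, when the alternative rule is
    enabled).  score = (#sensitive + 0.5 * #moderate) / #called.  Regimen
    drugs without a call (e.g. untestable prodrugs) are ignored; if no
    drug has a call the treatment is untestable.
    """
    if isinstance(calls, pd.DataFrame):
        calls = {(str(r.pdo_id), str(r.drug_id)): Label(r.label)
                 for r in calls.itertuples(index=False)}
    found = [calls[(treatment.pdo_id, d)] for d in treatment.drugs
             if (treatment.pdo_id, d) in calls]
    if not found:
        raise UntestableTreatmentError(
            f"no regimen drug of {treatment.patient_id} round"
            f" {treatment.round_index} has a call for PDO {treatment.pdo_id}")
    best = min(found, key=_LABEL_ORDER.__getitem__)
    n_sens = sum(1 for lab in found if lab is Label.SENSITIVE)
    n_mod = sum(1 for lab in found if lab is Label.MODERATE)
    score = (n_sens + 0.5 * n_mod) / len(found)
    good = best is Label.SENSITIVE or (
        moderate_counts_as_good and best is Label.MODERATE)
    return TreatmentPrediction(treatment, best, good, score, len(found))
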