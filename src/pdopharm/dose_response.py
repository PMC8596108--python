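"""Viability normalization, 4PL dose-response fitting and censored IC50s.

The screen reads raw luminescence; viability is anchored to the plate
controls (DMSO negative = 100%, high-dose bortezomib positive = 0%).
Dose-response curves follow the four-parameter logistic

    y(c) = bottom + (top - bottom) / (1 + (c / ec50)**hill)

and the IC50 is the *absolute* concentration at which the fitted curve
crosses 50% viability (not the relative-to-asymptote EC50).  Curves that
never cross 50% inside the tested range are censored to the range bound:
``at_max`` when the line stays above 50% (resistant), ``at_min`` when it
stays below (hypersensitive).

Combination screens fix one partner at its IC30 (70% residual viability)
and titrate the other; the additivity expectation is the Bliss-style
pointwise product of the single-agent curve with the partner's fractional
viability.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .io import PlateWell, Role, ValidationError

__all__ = [
    "Censor",
    "DoseResponseCurve",
    "FourPLFit",
    "IC50Record",
    "ComboCurve",
    "DegeneratePlateError",
    "InsufficientDataError",
    "four_pl",
    "normalize_viability",
    "FourParamLogistic",
    "fit_4pl",
    "extract_ic50",
    "replicate_qc",
    "predicted_additive",
    "combo_excess",
]


class DegeneratePlateError(ValueError):
    """Plate controls do not separate (negative mean <= positive mean)."""


class InsufficientDataError(ValueError):
    """Too few distinct concentrations (or replicates) for the operation."""


class Censor(str, enum.Enum):
    INTERIOR = "interior"
    AT_MAX = "at_max"
    AT_MIN = "at_min"


@dataclass
class DoseResponseCurve:
    """Normalized viability for one PDO x drug, replicates kept separate.

    ``viability`` has shape (n_concentrations, n_replicates) in percent;
    concentrations are strictly decreasing (highest dose first).
    """

    pdo_id: str
    drug_id: str
    concentrations: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.atleast_2d(np.asarray(self.viability, dtype=float))
        if self.viability.shape[0] != self.concentrations.size:
            raise ValidationError("viability rows must match concentrations")
        if not np.all(np.isfinite(self.viability)):
            raise ValidationError("viability values must be finite")
        if np.any(np.diff(self.concentrations) >= 0):
            raise ValidationError("concentrations must be strictly decreasing")

    @property
    def mean_viability(self) -> np.ndarray:
        return self.viability.mean(axis=1)

    @property
    def n_replicates(self) -> int:
        return self.viability.shape[1]

    @property
    def tested_range(self) -> tuple[float, float]:
        return float(self.concentrations.min()), float(self.concentrations.max())


@dataclass(frozen=True)
class FourPLFit:
    """Fitted 4PL parameters; ``flagged`` marks degenerate/non-converged fits."""

    top: float
    bottom: float
    hill: float
    ec50: float
    rss: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.top < self.bottom:
            raise ValidationError("top must be >= bottom")
        if not self.ec50 > 0:
            raise ValidationError("ec50 must be > 0")

    def predict(self, conc: np.ndarray | float) -> np.ndarray:
        return four_pl(np.asarray(conc, dtype=float), self.top, self.bottom,
                       self.hill, self.ec50)


@dataclass(frozen=True)
class IC50Record:
    pdo_id: str
    drug_id: str
    ic50: float
    censor: Censor


@dataclass
class ComboCurve:
    """Single-agent curve plus the fixed-partner additivity prediction."""

    gradient: DoseResponseCurve
    partner_id: str
    partner_viability: float
    predicted: np.ndarray
    observed: np.ndarray | None = None

    @property
    def excess(self) -> float:
        return combo_excess(self)


def four_pl(conc, top, bottom, hill, ec50):
    """Four-parameter logistic viability at concentration ``conc``."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ec50) ** hill)


# ---------------------------------------------------------------------------
# normalization


def normalize_viability(wells: Iterable[PlateWell],
                        mode: str = "two_anchor") -> list[DoseResponseCurve]:
    """Normalize one PDO's raw wells to percent viability.

    two_anchor (default): 100 * (signal - mean_pos) / (mean_neg - mean_pos),
    so the negative-control mean maps to 100% and the positive-control mean
    to 0%.  neg_only: 100 * signal / mean_neg (positive control unused).
    Values outside [0, 100] are kept as-is.
    """
    wells = list(wells)
    pdos = {w.pdo_id for w in wells}
    if len(pdos) != 1:
        raise ValidationError(f"normalize_viability expects one PDO, got {sorted(pdos)}")
    neg = [w.raw_signal for w in wells if w.role is Role.NEG_CONTROL]
    pos = [w.raw_signal for w in wells if w.role is Role.POS_CONTROL]
    if not neg:
        raise ValidationError("no negative-control wells on plate")
    if mode == "two_anchor" and not pos:
        raise ValidationError("no positive-control wells on plate")
    mean_neg = float(np.mean(neg))
    if mode == "two_anchor":
        mean_pos = float(np.mean(pos))
        if mean_neg <= mean_pos:
            raise DegeneratePlateError(
                f"negative-control mean ({mean_neg:.4g}) must exceed"
                f" positive-control mean ({mean_pos:.4g})")
    else:
        mean_pos = 0.0
        if mean_neg <= 0:
            raise DegeneratePlateError("negative-control mean must be positive")

    curves = []
    test = [w for w in wells if w.role is Role.TEST]
    drugs = sorted({w.drug_id for w in test})
    for drug in drugs:
        dw = [w for w in test if w.drug_id == drug]
        concs = np.array(sorted({w.conc for w in dw}, reverse=True))
        reps = sorted({w.replicate for w in dw})
        grid = np.full((concs.size, len(reps)), np.nan)
        for w in dw:
            i = int(np.argmin(np.abs(concs - w.conc)))
            j = reps.index(w.replicate)
            grid[i, j] = 100.0 * (w.raw_signal - mean_pos) / (mean_neg - mean_pos)
        if np.isnan(grid).any():
            raise ValidationError(
                f"incomplete replicate grid for {drug} on PDO {dw[0].pdo_id}")
        curves.append(DoseResponseCurve(dw[0].pdo_id, drug, concs, grid))
    return curves


# ---------------------------------------------------------------------------
# 4PL fitting


class FourParamLogistic(BaseEstimator):
    """Least-squares 4PL dose-response fit.

    Initialization scans a coarse grid over log10(ec50) x hill; top and
    bottom are profiled out by linear least squares at every grid point.
    The grid winner is refined by Nelder-Mead.  Replicates are fitted at
    the residual level (every well contributes a residual), not to the
    per-dose means.

    Parameters
    ----------
    hill_grid : candidate hill slopes for initialization.
    n_ec50 : grid resolution over log10(ec50); the grid spans the tested
        concentration range extended by ``ec50_pad`` decades on each side.
    maxiter : Nelder-Mead iteration cap; hitting it flags the fit.

    Attributes (after ``fit``)
    --------------------------
    top_, bottom_, hill_, ec50_, rss_ : fitted parameters and residual
        sum of squares; ``flagged_`` is True for degenerate or
        non-converged fits (flat curves with < ``min_span`` percent of
        dynamic range, or optimizer failure).
    """

    def __init__(self, hill_grid: Sequence[float] = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0),
                 n_ec50: int = 30, ec50_pad: float = 1.5, maxiter: int = 400,
                 min_span: float = 10.0):
        self.hill_grid = hill_grid
        self.n_ec50 = n_ec50
        self.ec50_pad = ec50_pad
        self.maxiter = maxiter
        self.min_span = min_span

    @staticmethod
    def _profile_rss(conc: np.ndarray, y: np.ndarray, hill: float,
                     ec50: float) -> tuple[float, float, float]:
        # y = bottom*(1-w) + top*w with w = 1/(1+(c/ec50)^hill): linear LS
        w = 1.0 / (1.0 + (conc / ec50) ** hill)
        A = np.column_stack([1.0 - w, w])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        bottom, top = float(coef[0]), float(coef[1])
        rss = float(np.sum((A @ coef - y) ** 2))
        return top, bottom, rss

    def fit(self, conc: np.ndarray, viability: np.ndarray) -> "FourParamLogistic":
        conc = np.asarray(conc, dtype=float).ravel()
        y = np.asarray(viability, dtype=float).ravel()
        if conc.size != y.size:
            raise ValidationError("conc and viability must have the same length")
        if np.unique(conc).size < 4:
            raise InsufficientDataError(
                f"need >= 4 distinct concentrations, got {np.unique(conc).size}")

        lo = np.log10(conc.min()) - self.ec50_pad
        hi = np.log10(conc.max()) + self.ec50_pad
        log_ec50_grid = np.linspace(lo, hi, self.n_ec50)

        best = None
        for hill in self.hill_grid:
            for le in log_ec50_grid:
                top, bottom, rss = self._profile_rss(conc, y, hill, 10.0 ** le)
                if best is None or rss < best[4]:
                    best = (top, bottom, hill, le, rss)
        top0, bottom0, hill0, le0, rss0 = best

        def objective(x):
            t, b, h, le = x
            with np.errstate(over="ignore"):
                pred = b + (t - b) / (1.0 + (conc / 10.0 ** le) ** h)
            return float(np.sum((pred - y) ** 2))

        res = minimize(objective, x0=[top0, bottom0, hill0, le0],
                       method="Nelder-Mead",
                       options={"maxiter": self.maxiter, "xatol": 1e-8,
                                "fatol": 1e-10})
        converged = bool(res.success)
        if res.fun <= rss0:
            t, b, h, le = res.x
        else:  # grid-best fallback
            t, b, h, le = top0, bottom0, hill0, le0
            res_fun = rss0
            converged = False
        if t < b:  # same curve with asymptotes swapped and slope negated
            t, b, h = b, t, -h
        self.top_ = float(t)
        self.bottom_ = float(b)
        self.hill_ = float(h)
        self.ec50_ = float(10.0 ** le)
        self.rss_ = float(min(res.fun, rss0))
        self.flagged_ = (not converged) or (self.top_ - self.bottom_ < self.min_span)
        return self

    def predict(self, conc: np.ndarray) -> np.ndarray:
        return four_pl(conc, self.top_, self.bottom_, self.hill_, self.ec50_)

    def to_fit(self) -> FourPLFit:
        return FourPLFit(self.top_, self.bottom_, self.hill_, self.ec50_,
                         self.rss_, self.flagged_)


def fit_4pl(curve: DoseResponseCurve, **params) -> FourPLFit:
    """Fit a 4PL to all replicate wells of one curve (residual-level pooling)."""
    conc = np.repeat(curve.concentrations, curve.n_replicates)
    y = curve.viability.ravel()
    return FourParamLogistic(**params).fit(conc, y).to_fit()


def extract_ic50(fit: FourPLFit, curve_or_range, tested_range=None) -> IC50Record:
    """IC50 = absolute 50%-viability crossing of the fitted curve, censored
    to the tested range when the curve never crosses 50% inside it."""
    if isinstance(curve_or_range, DoseResponseCurve):
        pdo_id, drug_id = curve_or_range.pdo_id, curve_or_range.drug_id
        lo, hi = curve_or_range.tested_range
    else:
        pdo_id, drug_id = "", ""
        lo, hi = curve_or_range
    if tested_range is not None:
        lo, hi = tested_range

    v_lo = float(fit.predict(lo))
    v_hi = float(fit.predict(hi))
    v_min, v_max = min(v_lo, v_hi), max(v_lo, v_hi)
    if v_min >= 50.0:
        return IC50Record(pdo_id, drug_id, hi, Censor.AT_MAX)
    if v_max <= 50.0:
        return IC50Record(pdo_id, drug_id, lo, Censor.AT_MIN)
    # crossing exists strictly inside the range; closed form for the 4PL
    ratio = (fit.top - fit.bottom) / (50.0 - fit.bottom) - 1.0
    ic50 = fit.ec50 * ratio ** (1.0 / fit.hill)
    ic50 = float(np.clip(ic50, np.nextafter(lo, hi), np.nextafter(hi, lo)))
    return IC50Record(pdo_id, drug_id, ic50, Censor.INTERIOR)


def replicate_qc(curve: DoseResponseCurve, cv_limit: float = 0.20):
    """Per-concentration replicate CV (sample sd / mean) and a pass flag.

    Fails when the median CV over concentrations exceeds ``cv_limit``.
    With a single replicate QC is skipped (returns None with a warning).
    """
    if curve.n_replicates < 2:
        warnings.warn(f"single replicate for {curve.pdo_id}/{curve.drug_id};"
                      " replicate QC skipped", stacklevel=2)
        return None
    means = curve.viability.mean(axis=1)
    sds = curve.viability.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means != 0, sds / np.abs(means), np.inf)
    passed = bool(np.median(cvs) <= cv_limit)
    return cvs, passed


def predicted_additive(curve: DoseResponseCurve, partner_id: str = "",
                       fixed_partner_viability: float = 0.70) -> ComboCurve:
    """Bliss-style additivity prediction for a fixed-partner combination:
    predicted viability(c) = single-agent mean viability(c) x partner
    fractional viability (0.70 when the partner sits at its IC30)."""
    if not 0 < fixed_partner_viability <= 1:
        raise ValueError("fixed_partner_viability must be in (0, 1]")
    predicted = curve.mean_viability * fixed_partner_viability
    return ComboCurve(curve, partner_id, fixed_partner_viability, predicted)


def combo_excess(combo: ComboCurve) -> float:
    """Mean (predicted - observed) viability over the shared dose grid;
    positive values mean the combination beats the additivity expectation."""
    if combo.observed is None:
        raise ValueError("combo has no observed combination series")
    observed = np.asarray(combo.observed, dtype=float)
    if observed.shape != combo.predicted.shape:
        raise ValueError(
            f"grid mismatch: observed {observed.shape} vs predicted"
            f" {combo.predicted.shape}")
    return float(np.mean(combo.predicted - observed))
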