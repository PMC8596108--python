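"""Synthetic screens, expression matrices, clinical and survival cohorts.

These generators emulate the statistical structure the downstream
analysis assumes, so every stage can be exercised and scored against a
known ground truth without any external data:

* a viability screen: per PDO x drug a true 4PL curve, read out on the
  panel's 7-point threefold series in triplicate with multiplicative
  lognormal noise (luminescence scales with cell number, so noise is
  CV-parameterized and multiplicative); DMSO negative controls sit at the
  no-drug plateau and 1 µM bortezomib positive controls near zero signal;
* a count matrix with a planted signature whose genes separate sensitive
  from resistant lines and track the planted log-IC50 monotonically;
* clinical treatment records drawn with the study's conditional response
  probabilities (71% good response when a regimen contains a sensitive
  drug; 93% progression when it contains neither a sensitive nor a
  moderate drug);
* exponential survival cohorts with a group hazard ratio and independent
  censoring.

Every generator returns a :class:`SimTruth` beside the data; recovery
tests may read the truth only for scoring, never for fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calls import Label
from .dose_response import Censor, four_pl
from .io import (
    MICROTUBULE_DRUGS,
    DrugPanelEntry,
    Outcome,
    PlateWell,
    Role,
    SurvivalRecord,
    TreatmentRecord,
)

__all__ = [
    "SimTruth",
    "simulate_screen",
    "simulate_expression",
    "simulate_clinic",
    "simulate_survival",
]


@dataclass
class SimTruth:
    """Ground truth written beside every simulated dataset.

    curves : per PDO x drug true 4PL parameters, the analytic IC50 and its
        censoring status within the tested range.
    pdo_latent : per-PDO latent microtubule-sensitivity factor (higher =
        more resistant) and the planted group where applicable.
    genes : per-gene signature membership and direction.
    treatments : per-treatment category ('sensitive' / 'moderate' /
        'none') and the response propensity it was drawn with.
    """

    curves: pd.DataFrame | None = None
    pdo_latent: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None
    mt_ic50: pd.DataFrame | None = None
    treatments: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        blob = {"params": self.params}
        for name in ("curves", "pdo_latent", "genes", "treatments"):
            df = getattr(self, name)
            if df is not None:
                blob[name] = df.to_dict(orient="list")
        if self.mt_ic50 is not None:
            blob["mt_ic50"] = {
                "index": list(self.mt_ic50.index),
                "columns": list(self.mt_ic50.columns),
                "values": self.mt_ic50.values.tolist(),
            }
        with open(path, "w") as fh:
            json.dump(blob, fh, indent=1, default=str)


def _true_ic50(top, bottom, hill, ec50, cmin, cmax):
    """Analytic 50%-crossing of a 4PL, censored to [cmin, cmax]."""
    if bottom >= 50.0:  # plateau above 50: never inhibited to half
        return cmax, Censor.AT_MAX
    if top <= 50.0:  # whole curve below 50: hypersensitive
        return cmin, Censor.AT_MIN
    ic50 = ec50 * ((top - bottom) / (50.0 - bottom) - 1.0) ** (1.0 / hill)
    if ic50 > cmax:
        return cmax, Censor.AT_MAX
    if ic50 < cmin:
        return cmin, Censor.AT_MIN
    return float(ic50), Censor.INTERIOR


def simulate_screen(panel: Sequence[DrugPanelEntry], n_pdos: int = 76,
                    noise_cv: float = 0.10, seed: int = 0,
                    signal_scale: float = 1e5, n_control_wells: int = 16,
                    mt_effect: float = 1.0
                    ) -> tuple[list[PlateWell], SimTruth]:
    """Simulate raw plate wells for a full screen plus the ground truth.

    Per PDO x drug, a true 4PL curve is drawn: top ~ N(100, 3), bottom ~
    U(0, 10), hill ~ U(0.8, 2.5) and log10 ec50 composed of a drug potency
    term, a general per-PDO sensitivity shift, a shared microtubule latent
    factor (weight ``mt_effect`` on the six microtubule drugs, which makes
    their responses correlated across the cohort) and residual scatter.
    Raw signal = signal_scale x viability-fraction x lognormal(cv).
    """
    if n_pdos < 1:
        raise ValueError("n_pdos must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    pdo_ids = [f"PDO{i:03d}" for i in range(1, n_pdos + 1)]

    sigma = np.sqrt(np.log1p(noise_cv ** 2))  # lognormal with unit mean

    def noise(size):
        if noise_cv == 0:
            return np.ones(size)
        return rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=size)

    drug_potency = {e.drug_id: rng.uniform(-7.3, -4.7) for e in panel}
    pdo_shift = rng.normal(0.0, 0.3, size=n_pdos)
    mt_latent = rng.normal(0.0, 1.0, size=n_pdos)

    wells: list[PlateWell] = []
    rows = []
    for i, pdo in enumerate(pdo_ids):
        for entry in panel:
            concs = entry.concentrations
            top = rng.normal(100.0, 3.0)
            bottom = rng.uniform(0.0, 10.0)
            hill = rng.uniform(0.8, 2.5)
            le = drug_potency[entry.drug_id] + pdo_shift[i] + rng.normal(0, 0.4)
            if entry.drug_id in MICROTUBULE_DRUGS:
                le += mt_effect * mt_latent[i]
            ec50 = 10.0 ** le
            viab = four_pl(concs, top, bottom, hill, ec50) / 100.0
            for rep in range(1, 4):
                sig = signal_scale * np.clip(viab, 0.0, None) * noise(concs.size)
                wells += [
                    PlateWell(pdo, entry.drug_id, float(c), rep, float(s),
                              Role.TEST)
                    for c, s in zip(concs, sig)
                ]
            ic50, cens = _true_ic50(top, bottom, hill, ec50,
                                    entry.min_conc, entry.top_conc)
            rows.append((pdo, entry.drug_id, top, bottom, hill, ec50, ic50,
                         cens.value))
        # plate controls: DMSO at the no-drug plateau, 1 µM bortezomib ~ 0
        for rep, s in enumerate(signal_scale * noise(n_control_wells), 1):
            wells.append(PlateWell(pdo, "", 0.0, rep, float(s),
                                   Role.NEG_CONTROL))
        for rep, s in enumerate(
                signal_scale * 0.02 * noise(n_control_wells), 1):
            wells.append(PlateWell(pdo, "", 0.0, rep, float(s),
                                   Role.POS_CONTROL))

    curves = pd.DataFrame(rows, columns=["pdo_id", "drug_id", "top", "bottom",
                                         "hill", "ec50", "ic50_true",
                                         "censor_true"])
    latent = pd.DataFrame({"pdo_id": pdo_ids, "mt_latent": mt_latent,
                           "pdo_shift": pdo_shift})
    truth = SimTruth(curves=curves, pdo_latent=latent,
                     params={"n_pdos": n_pdos, "noise_cv": noise_cv,
                             "seed": seed, "mt_effect": mt_effect})
    return wells, truth


def simulate_expression(n_genes: int = 2000, n_pdos: int = 20,
                        n_signature: int = 100, effect_log2fc: float = 2.0,
                        seed: int = 0, dispersion: float = 0.05,
                        lib_spread_log2: float = 1.0
                        ) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a genes x samples count matrix with a planted signature.

    Half of the lines are planted as microtubule-drug sensitive, half as
    resistant; signature genes (half up-, half down-in-sensitive) have
    their log2 mean shifted by ``effect_log2fc`` in the sensitive lines.
    Each line carries a planted six-drug IC50 table whose log10 values
    separate the groups, giving signature genes a monotone association
    with IC50.  Counts are gamma-Poisson (negative-binomial-like) with
    the given dispersion; library-size factors span exactly
    ``lib_spread_log2`` log2 units (>= 2-fold by default).
    """
    if n_signature > n_genes:
        raise ValueError("n_signature must be <= n_genes")
    if n_pdos < 2:
        raise ValueError("n_pdos must be >= 2")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    pdos = [f"PDO{i:03d}" for i in range(1, n_pdos + 1)]

    sensitive = np.zeros(n_pdos, dtype=bool)
    sensitive[rng.permutation(n_pdos)[: n_pdos // 2]] = True

    # planted six-drug IC50s (molar): sensitive lines ~10x lower, with
    # within-group spread so per-drug rankings stay stable across drugs
    base_le = np.where(sensitive, rng.uniform(-7.0, -6.0, n_pdos),
                       rng.uniform(-5.5, -4.5, n_pdos))
    mt_ic50 = pd.DataFrame(
        {d: 10.0 ** (base_le + rng.normal(0, 0.05, n_pdos))
         for d in MICROTUBULE_DRUGS},
        index=pdos)

    base_log2 = rng.uniform(1.0, 9.0, size=n_genes)
    sig_idx = rng.choice(n_genes, size=n_signature, replace=False)
    # signature genes are planted at detectable expression: below ~16 mean
    # counts Poisson shot noise swamps any fold change, and real response
    # signatures are drawn from robustly expressed genes
    base_log2[sig_idx] = rng.uniform(4.0, 9.0, size=n_signature)
    direction = np.zeros(n_genes)
    direction[sig_idx[: n_signature // 2]] = 1.0
    direction[sig_idx[n_signature // 2:]] = -1.0

    mu_log2 = base_log2[:, None] + direction[:, None] * effect_log2fc \
        * sensitive[None, :].astype(float)
    lib = 2.0 ** rng.permutation(
        np.linspace(-lib_spread_log2 / 2, lib_spread_log2 / 2, n_pdos))
    mean = (2.0 ** mu_log2) * lib[None, :]
    if dispersion > 0:
        shape = 1.0 / dispersion
        mean = rng.gamma(shape, mean / shape)
    counts = pd.DataFrame(rng.poisson(mean), index=genes, columns=pdos)

    gene_truth = pd.DataFrame({
        "gene_id": genes,
        "is_signature": direction != 0,
        "direction": np.where(direction > 0, "up_in_sensitive",
                              np.where(direction < 0, "down_in_sensitive", "")),
    })
    latent = pd.DataFrame({"pdo_id": pdos,
                           "group": np.where(sensitive, "pan_sensitive",
                                             "pan_resistant"),
                           "log10_ic50": base_le})
    truth = SimTruth(genes=gene_truth, pdo_latent=latent, mt_ic50=mt_ic50,
                     params={"n_genes": n_genes, "n_pdos": n_pdos,
                             "n_signature": n_signature,
                             "effect_log2fc": effect_log2fc, "seed": seed,
                             "dispersion": dispersion})
    return counts, truth


def simulate_clinic(calls: pd.DataFrame, n_treatments: int = 100,
                    p_good_given_sensitive: float = 0.71,
                    p_pd_given_none: float = 0.93,
                    p_good_given_moderate: float = 0.5,
                    max_drugs: int = 3, seed: int = 0
                    ) -> tuple[list[TreatmentRecord], SimTruth]:
    """Simulate treatment records whose outcomes follow the concordance
    probabilities, conditioning on the PDO call profile (the causal
    direction the concordance analysis assumes).

    ``calls`` is a long table (pdo_id, drug_id, label).  Each treatment
    samples a PDO, a regimen of 1..max_drugs called drugs, and then an
    outcome: good (PR or SD) with probability ``p_good_given_sensitive``
    when the regimen has a sensitive drug, ``p_good_given_moderate`` when
    its best call is moderate, and ``1 - p_pd_given_none`` otherwise.
    """
    for p in (p_good_given_sensitive, p_pd_given_none, p_good_given_moderate):
        if not 0 <= p <= 1:
            raise ValueError("probabilities must be in [0, 1]")
    if calls.empty:
        raise ValueError("calls table is empty")
    rng = np.random.default_rng(seed)
    by_pdo = {pdo: dict(zip(sub["drug_id"], sub["label"]))
              for pdo, sub in calls.groupby("pdo_id")}
    pdos = sorted(by_pdo)

    records: list[TreatmentRecord] = []
    rows = []
    for k in range(n_treatments):
        pdo = pdos[rng.integers(len(pdos))]
        available = sorted(by_pdo[pdo])
        n_drugs = int(rng.integers(1, min(max_drugs, len(available)) + 1))
        regimen = tuple(sorted(rng.choice(available, size=n_drugs,
                                          replace=False)))
        labels = [Label(by_pdo[pdo][d]) for d in regimen]
        if Label.SENSITIVE in labels:
            category, p_good = "sensitive", p_good_given_sensitive
        elif Label.MODERATE in labels:
            category, p_good = "moderate", p_good_given_moderate
        else:
            category, p_good = "none", 1.0 - p_pd_given_none
        good = rng.random() < p_good
        outcome = (Outcome.PR if rng.random() < 0.5 else Outcome.SD) if good \
            else Outcome.PD
        records.append(TreatmentRecord(f"Pat{k + 1:04d}", pdo, 1, regimen,
                                       outcome))
        rows.append((f"Pat{k + 1:04d}", category, p_good))
    truth = SimTruth(
        treatments=pd.DataFrame(rows, columns=["patient_id", "category",
                                               "p_good"]),
        params={"n_treatments": n_treatments,
                "p_good_given_sensitive": p_good_given_sensitive,
                "p_pd_given_none": p_pd_given_none,
                "p_good_given_moderate": p_good_given_moderate, "seed": seed})
    return records, truth


def simulate_survival(n_per_group: int = 200, hazard_ratio: float = 3.0,
                      censor_rate: float = 0.2, baseline_hazard: float = 0.05,
                      seed: int = 0) -> list[SurvivalRecord]:
    """Exponential event times with a group hazard ratio and independent
    exponential censoring calibrated to the requested censored fraction.

    The ``sensitive_signature`` group has the baseline hazard; the
    ``non_sensitive`` group's hazard is multiplied by ``hazard_ratio``.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    records: list[SurvivalRecord] = []
    i = 0
    for group, hazard in (("sensitive_signature", baseline_hazard),
                          ("non_sensitive", baseline_hazard * hazard_ratio)):
        t_event = rng.exponential(1.0 / hazard, size=n_per_group)
        if censor_rate > 0:
            c_hazard = hazard * censor_rate / (1.0 - censor_rate)
            t_cens = rng.exponential(1.0 / c_hazard, size=n_per_group)
        else:
            t_cens = np.full(n_per_group, np.inf)
        for te, tc in zip(t_event, t_cens):
            i += 1
            records.append(SurvivalRecord(f"S{i:04d}", float(min(te, tc)),
                                          bool(te <= tc), group))
    return records
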