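"""End-to-end pipeline: each stage reads/writes plain-text artifacts.

Stage order (each stage's inputs are earlier stages' outputs):

    simulate -> plates.tsv, counts.tsv, mt_ic50.tsv, survival.tsv, truth_*.json
    fit      -> fits.tsv, ic50.tsv
    classify -> calls.tsv
    combo    -> combo.tsv
    signature-> signature.tsv, groups.tsv, model.json
    survival -> km.tsv, logrank.json
    concord  -> treatments.tsv, treatment_predictions.tsv, concordance.json
    report   -> report.json

All randomness flows from ``RunConfig.seed``; per-stage seeds are derived
deterministically, so a fixed seed reproduces every artifact byte for
byte.  Default problem sizes (20 lines on the 49-drug panel for the
screen; 2000 genes on 20 lines for expression; 200 subjects per survival
arm; 300 treatments) keep a full run to about a minute while leaving
every stage's statistics well-determined.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import calls as calls_mod
from . import dose_response as dr
from . import io
from . import outcomes as out_mod
from . import signature as sig_mod
from . import simulate as sim

logger = logging.getLogger(__name__)

__all__ = ["DependencyError", "stage_simulate", "stage_fit", "stage_classify",
           "stage_combo", "stage_signature", "stage_survival",
           "stage_concord", "stage_report", "run_pipeline"]


class DependencyError(RuntimeError):
    """A stage was invoked before the stage that produces its inputs."""


def _stage_seed(seed: int, k: int) -> int:
    return int((seed * 1000003 + k) % (2 ** 31))


def _need(outdir: Path, name: str, producer: str) -> Path:
    path = outdir / name
    if not path.exists():
        raise DependencyError(
            f"missing {name}: run the '{producer}' stage first")
    return path


def stage_simulate(config: io.RunConfig, outdir: Path, n_pdos: int = 20,
                   n_genes: int = 2000, n_expr_pdos: int = 20,
                   n_signature: int = 100, effect_log2fc: float = 2.0,
                   n_per_group: int = 200, hazard_ratio: float = 3.0,
                   censor_rate: float = 0.2) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    panel = io.default_panel()
    io.write_panel(panel, outdir / "panel.yaml")

    wells, truth = sim.simulate_screen(panel, n_pdos=n_pdos,
                                       noise_cv=config.noise_cv,
                                       seed=_stage_seed(config.seed, 1))
    io.write_plate_table(wells, outdir / "plates.tsv")
    truth.to_json(outdir / "truth_screen.json")

    counts, etruth = sim.simulate_expression(
        n_genes=n_genes, n_pdos=n_expr_pdos, n_signature=n_signature,
        effect_log2fc=effect_log2fc, seed=_stage_seed(config.seed, 2))
    io.write_table(counts.reset_index(names="gene_id"), outdir / "counts.tsv")
    io.write_table(etruth.mt_ic50.reset_index(names="pdo_id"),
                   outdir / "mt_ic50.tsv")
    etruth.to_json(outdir / "truth_expression.json")

    surv = sim.simulate_survival(n_per_group=n_per_group,
                                 hazard_ratio=hazard_ratio,
                                 censor_rate=censor_rate,
                                 seed=_stage_seed(config.seed, 3))
    io.write_survival(surv, outdir / "survival.tsv")


def stage_fit(config: io.RunConfig, outdir: Path) -> None:
    plates = _need(outdir, "plates.tsv", "simulate")
    panel = io.read_panel(_need(outdir, "panel.yaml", "simulate"))
    wells = io.read_plate_table(plates, panel)
    by_pdo: dict[str, list[io.PlateWell]] = {}
    for w in wells:
        by_pdo.setdefault(w.pdo_id, []).append(w)

    fit_rows, ic50_rows = [], []
    for pdo in sorted(by_pdo):
        curves = dr.normalize_viability(by_pdo[pdo], mode=config.normalization)
        for curve in curves:
            qc = dr.replicate_qc(curve, config.qc_cv_limit)
            qc_pass = qc[1] if qc is not None else True
            fit = dr.fit_4pl(curve)
            rec = dr.extract_ic50(fit, curve)
            fit_rows.append((pdo, curve.drug_id, fit.top, fit.bottom,
                             fit.hill, fit.ec50, fit.rss, int(fit.flagged),
                             int(qc_pass)))
            ic50_rows.append((pdo, curve.drug_id, rec.ic50, rec.censor.value))
    io.write_table(pd.DataFrame(
        fit_rows, columns=["pdo_id", "drug_id", "top", "bottom", "hill",
                           "ec50", "rss", "flagged", "qc_pass"]),
        outdir / "fits.tsv")
    io.write_table(pd.DataFrame(
        ic50_rows, columns=["pdo_id", "drug_id", "ic50_molar", "censor"]),
        outdir / "ic50.tsv")


def stage_classify(config: io.RunConfig, outdir: Path) -> None:
    ic50 = io.read_table(_need(outdir, "ic50.tsv", "fit"))
    calls, errors = calls_mod.call_matrix(ic50, config.tertile_fraction)
    io.write_table(calls, outdir / "calls.tsv")
    if errors:
        (outdir / "calls_errors.json").write_text(
            json.dumps(errors, indent=1, sort_keys=True))


def stage_combo(config: io.RunConfig, outdir: Path,
                n_pairs: int = 6) -> None:
    """Predicted-additive curves for a few gradient/partner drug pairs,
    with a simulated Bliss-independent observed combination."""
    plates = _need(outdir, "plates.tsv", "simulate")
    panel = io.read_panel(_need(outdir, "panel.yaml", "simulate"))
    wells = io.read_plate_table(plates, panel)
    pdos = sorted({w.pdo_id for w in wells})
    rng = np.random.default_rng(_stage_seed(config.seed, 4))
    rows = []
    for k in range(n_pairs):
        pdo = pdos[k % len(pdos)]
        curves = dr.normalize_viability(
            [w for w in wells if w.pdo_id == pdo], mode=config.normalization)
        gradient = curves[k % len(curves)]
        partner = curves[(k + 7) % len(curves)].drug_id
        combo = dr.predicted_additive(gradient, partner,
                                      config.fixed_partner_viability)
        # Bliss-independent observation: product plus replicate-level noise
        obs = combo.predicted * rng.lognormal(
            -0.005, 0.1 / np.sqrt(gradient.n_replicates),
            size=combo.predicted.size)
        combo.observed = obs
        for c, p, o in zip(gradient.concentrations, combo.predicted, obs):
            rows.append((pdo, gradient.drug_id, partner, c, p, o))
        rows_excess = combo.excess
        rows.append((pdo, gradient.drug_id, partner, np.nan, np.nan,
                     rows_excess))
    io.write_table(pd.DataFrame(
        rows, columns=["pdo_id", "gradient_drug", "partner_drug",
                       "conc_molar", "predicted", "observed_or_excess"]),
        outdir / "combo.tsv")


def stage_signature(config: io.RunConfig, outdir: Path) -> None:
    counts = io.read_table(_need(outdir, "counts.tsv", "simulate")) \
        .set_index("gene_id")
    mt_ic50 = io.read_table(_need(outdir, "mt_ic50.tsv", "simulate")) \
        .set_index("pdo_id")
    expr = sig_mod.normalize_counts(counts)

    # pan-sensitive / pan-resistant: tertile calls per microtubule drug,
    # groups are the lines sensitive (resp. resistant) to all six drugs
    long = mt_ic50.reset_index().melt(id_vars="pdo_id", var_name="drug_id",
                                      value_name="ic50_molar")
    long["censor"] = "interior"
    mt_calls, _ = calls_mod.call_matrix(long, config.tertile_fraction)
    pivot = mt_calls.pivot(index="pdo_id", columns="drug_id", values="label")
    pan = pd.Series("neither", index=pivot.index)
    pan[(pivot == "sensitive").all(axis=1)] = "pan_sensitive"
    pan[(pivot == "resistant").all(axis=1)] = "pan_resistant"

    selector = sig_mod.SignatureSelector(
        de_fdr_max=config.de_fdr_max, de_fc_min=config.de_fc_min,
        rho_min=config.rho_min)
    selector.fit(expr.T, pan, mt_ic50)
    io.write_table(selector.signature_frame(), outdir / "signature.tsv")

    if len(selector.gene_ids_) >= 2:
        groups = sig_mod.cluster_pdos(selector.transform(expr.T),
                                      selector.signature_)
        io.write_table(groups.rename_axis("pdo_id").reset_index(),
                       outdir / "groups.tsv")
        model = sig_mod.train_classifier(selector.transform(expr.T), groups)
        (outdir / "model.json").write_text(json.dumps({
            "genes": model.feature_names_,
            "coef": model.coef_.tolist(),
            "intercept": model.intercept_,
            "center": model.center_.tolist(),
            "scale": model.scale_.tolist(),
            "classes": model.classes_.tolist(),
        }, indent=1))
    else:
        logger.warning("signature has < 2 genes; clustering skipped")


def stage_survival(config: io.RunConfig, outdir: Path) -> None:
    records = io.read_survival(_need(outdir, "survival.tsv", "simulate"))
    groups = sorted({r.group for r in records})
    rows = []
    for g in groups:
        km = out_mod.km_fit(records, g)
        for t, s, n in zip(km.times, km.survival, km.at_risk):
            rows.append((g, t, s, n))
    io.write_table(pd.DataFrame(rows, columns=["group", "time", "survival",
                                               "at_risk"]),
                   outdir / "km.tsv")
    stat, p = out_mod.logrank_test(records)
    (outdir / "logrank.json").write_text(
        json.dumps({"statistic": stat, "p_value": p}, indent=1))


def stage_concord(config: io.RunConfig, outdir: Path,
                  n_treatments: int = 300) -> None:
    calls = io.read_table(_need(outdir, "calls.tsv", "classify"))
    tpath = outdir / "treatments.tsv"
    if tpath.exists():
        treatments = io.read_treatments(tpath)
    else:
        treatments, ttruth = sim.simulate_clinic(
            calls, n_treatments=n_treatments,
            seed=_stage_seed(config.seed, 5))
        io.write_treatments(treatments, tpath)
        ttruth.to_json(outdir / "truth_clinic.json")

    call_map = {(str(r.pdo_id), str(r.drug_id)): calls_mod.Label(r.label)
                for r in calls.itertuples(index=False)}
    preds, skipped = [], 0
    for t in treatments:
        try:
            preds.append(calls_mod.predict_treatment(
                t, call_map, config.moderate_counts_as_good))
        except calls_mod.UntestableTreatmentError:
            skipped += 1
    if skipped:
        logger.info("%d untestable treatment(s) excluded", skipped)
    io.write_table(pd.DataFrame(
        [(p.treatment.patient_id, p.treatment.pdo_id,
          p.treatment.round_index, "+".join(p.treatment.drugs),
          p.best_call.value, int(p.predicted_good), p.score,
          p.treatment.outcome.value) for p in preds],
        columns=["patient_id", "pdo_id", "round_index", "drugs", "best_call",
                 "predicted_good", "score", "outcome"]),
        outdir / "treatment_predictions.tsv")

    summary = out_mod.evaluate_concordance(
        preds, bootstrap_reps=config.bootstrap_reps, ci_level=config.ci_level,
        seed=_stage_seed(config.seed, 6))
    blob = {
        "n": summary.n, "tp": summary.tp, "fn": summary.fn,
        "fp": summary.fp, "tn": summary.tn,
        "accuracy": summary.accuracy, "sensitivity": summary.sensitivity,
        "specificity": summary.specificity, "auc": summary.auc,
        "ci": {k: list(v) for k, v in summary.ci.items()},
        "chi2_p": summary.chi2_p,
        "n_excluded_unknown": summary.n_excluded_unknown,
        "n_untestable": skipped,
    }
    (outdir / "concordance.json").write_text(json.dumps(blob, indent=1))


def stage_report(config: io.RunConfig, outdir: Path) -> None:
    report: dict = {"config": config.to_dict(),
                    "config_hash": config.config_hash()}
    for name in ("concordance.json", "logrank.json"):
        path = outdir / name
        if path.exists():
            report[name.removesuffix(".json")] = json.loads(path.read_text())
    for name in ("ic50.tsv", "calls.tsv", "signature.tsv"):
        path = outdir / name
        if path.exists():
            report[f"n_rows_{name.removesuffix('.tsv')}"] = \
                int(len(io.read_table(path)))
    (outdir / "report.json").write_text(json.dumps(report, indent=1,
                                                   sort_keys=True))


def run_pipeline(config: io.RunConfig, outdir: str | Path, **sim_kw) -> Path:
    """Run every stage in order; returns the output directory."""
    outdir = Path(outdir)
    logger.info("pipeline seed=%d config=%s", config.seed,
                config.config_hash())
    stage_simulate(config, outdir, **sim_kw)
    stage_fit(config, outdir)
    stage_classify(config, outdir)
    stage_combo(config, outdir)
    stage_signature(config, outdir)
    stage_survival(config, outdir)
    stage_concord(config, outdir)
    stage_report(config, outdir)
    return outdir
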