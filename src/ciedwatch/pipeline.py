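"""End-to-end pipeline: simulate -> extract flags -> fit -> predict ->
triage -> evaluate, with every artifact written under one output directory.

The run mirrors a development/validation design: a model is fit on the
development cohort's flags against its ground-truth labels, applied
out-of-sample to the validation cohort, a review queue is drawn at the
threshold, and validation metrics are computed over the queued (reviewed)
cases only — the same partial-verification arithmetic a real deployment
would face.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import pandas as pd

import ciedwatch.evaluation as evaluation
from ciedwatch.triage import fit as fit_model
from ciedwatch.triage import predict_frame
from ciedwatch.triage import triage as draw_queue
from ciedwatch.triage import SeparationError
from ciedwatch.config import AppConfig
from ciedwatch.emr import write_cohort, write_labels
from ciedwatch.flags import build_flag_vectors, flag_prevalence, flags_frame
from ciedwatch.synth import SimulatedCohort, end_to_end_fixture

logger = logging.getLogger(__name__)


def write_abstractions(abstractions, path: Union[str, Path]) -> None:
    rows = [a.model_dump() for a in abstractions]
    pd.DataFrame(rows).sort_values("procedure_id").to_csv(
        Path(path), index=False, lineterminator="\n")


def run_pipeline(config: AppConfig, out_dir: Union[str, Path],
                 seed: Optional[int] = None) -> dict:
    """Run the full surveillance pipeline; returns the report dict.

    ``seed`` overrides the config's simulation seed and also seeds the
    review-queue draw, so one integer fixes the whole run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation if seed is None else config.simulation.model_copy(
        update={"seed": int(seed)})
    queue_seed = sim.seed

    logger.info("simulating development + validation cohorts (n=%d each, seed=%d)",
                sim.n_procedures, sim.seed)
    dev, val = end_to_end_fixture(sim)
    for name, part in (("dev", dev), ("val", val)):
        d = out / name
        write_cohort(part.cohort, d)
        write_labels(part.labels, d / "truth.csv")
        write_abstractions(part.abstractions, d / "abstractions.csv")

    ruleset = config.compiled_ruleset()
    logger.info("extracting flags")
    dev_flags = flags_frame(build_flag_vectors(dev.cohort, config.flags, ruleset))
    val_flags = flags_frame(build_flag_vectors(val.cohort, config.flags, ruleset))
    dev_flags.to_csv(out / "flags_dev.csv", index=False, lineterminator="\n")
    val_flags.to_csv(out / "flags_val.csv", index=False, lineterminator="\n")
    flag_prevalence(dev_flags).to_csv(out / "flag_prevalence_dev.csv",
                                      index=False, lineterminator="\n")

    logger.info("fitting triage model on development cohort")
    try:
        model = fit_model(
            dev_flags, dev.labels, covariates=config.model.covariates,
            threshold=config.model.threshold, firth=config.model.firth,
            tol=config.model.tol, maxiter=config.model.maxiter)
    except SeparationError as e:
        # rare flags can quasi-separate a finite cohort; Firth's penalized
        # likelihood always has a finite maximizer
        logger.warning("plain MLE separated (%s); refitting with Firth", e)
        model = fit_model(
            dev_flags, dev.labels, covariates=config.model.covariates,
            threshold=config.model.threshold, firth=True,
            tol=config.model.tol, maxiter=config.model.maxiter)
    model.to_json(out / "model.json")
    model.or_table.to_csv(out / "odds_ratios.csv", index=False,
                          lineterminator="\n")

    logger.info("predicting + triaging validation cohort")
    preds = predict_frame(model, val_flags)
    queue = draw_queue(
        preds, threshold=model.threshold,
        above_fraction=config.triage.above_fraction,
        below_fraction=config.triage.below_fraction, seed=queue_seed)
    queue.to_csv(out / "triage.csv", index=False, lineterminator="\n")

    logger.info("evaluating on reviewed validation cases")
    # validation C statistic: refit on the reviewed validation cases
    reviewed_ids = set(queue.loc[queue["selected_for_review"], "procedure_id"])
    val_mask = val_flags["procedure_id"].isin(reviewed_ids)
    c_val = None
    val_rev_flags = val_flags.loc[val_mask].reset_index(drop=True)
    val_rev_labels = [l for l in val.labels if l.procedure_id in reviewed_ids]
    try:
        try:
            val_refit = fit_model(val_rev_flags, val_rev_labels,
                                  covariates=config.model.covariates,
                                  firth=config.model.firth)
        except SeparationError:
            val_refit = fit_model(val_rev_flags, val_rev_labels,
                                  covariates=config.model.covariates,
                                  firth=True)
        c_val = val_refit.diagnostics.c_statistic
    except Exception as e:  # tiny queues may still defeat the refit
        logger.warning("validation refit failed (%s); C statistic omitted", e)
    report = evaluation.evaluate(
        val.labels, queue, threshold=model.threshold, c_statistic=c_val,
        band_edges=config.evaluation.band_edges)

    report_dict = report.to_dict()
    report_dict["development"] = {
        "c_statistic": round(model.diagnostics.c_statistic, 4),
        "n": model.fitted_on["n"],
        "infections": model.fitted_on["positives"],
    }
    report.band_table.to_csv(out / "band_table.csv", index=False,
                             lineterminator="\n")
    report.metrics.as_frame().to_csv(out / "metrics.csv", index=False,
                                     lineterminator="\n")
    report.roc_curve.to_csv(out / "roc.csv", index=False, lineterminator="\n")
    (out / "report.json").write_text(
        json.dumps(report_dict, indent=2, sort_keys=True) + "\n")
    (out / "effective_config.yaml").write_text(config.dump_yaml())
    logger.info("pipeline complete: %s", out)
    return report_dict
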