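"""Logistic triage model: fit, predict, threshold, and review-queue sampling.

The model is a plain fixed-effects binomial-logit GLM over the per-procedure
flag vector.  Fitted coefficients are log-odds; exp(coefficient) is the
odds ratio reported with Wald 95% CIs.  The default covariate set is the
one that matters for device-infection triage: 90-day mortality, congestive
heart failure, solid tumor without metastasis, the CIED-infection and SSI
diagnosis-code flags, the two antibiotic-class indicators (reference: no
qualifying antibiotics), a positive cardiac microbiology specimen, and the
two clinical-note keyword flags (post-procedure infection documentation as
a positive predictor, pre-procedure infection history as a negative one).

Cases scoring at or above the review threshold (default 0.10 predicted
probability) are eligible for manual record review; the queue is drawn by
seeded simple random sampling within the above- and below-threshold strata
(defaults: 80% of above-threshold cases, 1% of the rest).

Maximum likelihood is fit by IRLS via statsmodels; optional Firth
bias-reduction (Jeffreys-prior penalized likelihood, implemented here) is
available for sparse flags near separation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from ciedwatch.emr import ReviewLabel
from ciedwatch.evaluation import mann_whitney_auc
from ciedwatch.flags import FlagVector

DEFAULT_COVARIATES: tuple[str, ...] = (
    "died_90d",
    "congestive_heart_failure",
    "solid_tumor_without_metastasis",
    "icd_cied_infection",
    "icd_ssi",
    "antibiotic_staph_directed",
    "antibiotic_non_staph",
    "micro_cardiac_pos",
    "note_infection_post",
    "note_infection_pre",
)

DEFAULT_THRESHOLD = 0.10


class SeparationError(RuntimeError):
    """The likelihood has no finite maximum (complete or quasi-separation)."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


def design_matrix(flags: Union[pd.DataFrame, FlagVector, Mapping],
                  covariates: Sequence[str] = DEFAULT_COVARIATES) -> pd.DataFrame:
    """Numeric design matrix (no intercept column) from flag vectors.

    The categorical ``antibiotic_class`` expands into the two indicator
    covariates ``antibiotic_staph_directed`` and ``antibiotic_non_staph``
    against the reference level "none".  Raises ValueError naming any
    covariate that cannot be derived from the input.
    """
    if isinstance(flags, FlagVector):
        flags = pd.DataFrame([vars(flags)])
    elif isinstance(flags, Mapping):
        flags = pd.DataFrame([dict(flags)])
    cols = {}
    for name in covariates:
        if name == "antibiotic_staph_directed":
            if "antibiotic_class" not in flags:
                raise ValueError("covariate missing from flag vector: antibiotic_class")
            cols[name] = (flags["antibiotic_class"] == "staph_directed").astype(float)
        elif name == "antibiotic_non_staph":
            if "antibiotic_class" not in flags:
                raise ValueError("covariate missing from flag vector: antibiotic_class")
            cols[name] = (flags["antibiotic_class"] == "non_staph").astype(float)
        elif name in flags.columns:
            cols[name] = flags[name].astype(float)
        else:
            raise ValueError(f"covariate missing from flag vector: {name}")
    return pd.DataFrame(cols, index=flags.index)


@dataclass
class FitDiagnostics:
    converged: bool
    iterations: int
    loglik: float
    c_statistic: float
    method: str = "irls"


@dataclass
class TriageModel:
    """Fitted (or externally supplied) logistic coefficients + threshold."""

    covariates: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    threshold: float = DEFAULT_THRESHOLD
    diagnostics: Optional[FitDiagnostics] = None
    or_table: Optional[pd.DataFrame] = None
    fitted_on: dict = field(default_factory=dict)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        beta = np.array([self.coefficients[c] for c in self.covariates])
        return self.intercept + X[list(self.covariates)].to_numpy() @ beta

    def to_json(self, path: Union[str, Path]) -> None:
        obj = {
            "covariates": list(self.covariates),
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "threshold": self.threshold,
            "fitted_on": self.fitted_on,
        }
        Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "TriageModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            covariates=tuple(obj["covariates"]),
            coefficients={k: float(v) for k, v in obj["coefficients"].items()},
            intercept=float(obj["intercept"]),
            threshold=float(obj.get("threshold", DEFAULT_THRESHOLD)),
            fitted_on=obj.get("fitted_on", {}),
        )


def _separating_covariates(X: np.ndarray, y: np.ndarray,
                           names: Sequence[str]) -> list[str]:
    """Covariates whose support perfectly predicts the outcome — the usual
    culprits when the MLE diverges on sparse flags."""
    out = []
    if len(np.unique(y)) < 2:
        return out
    for j, name in enumerate(names):
        on = X[:, j] > 0.5
        if on.any() and not on.all():
            if (y[on].min() == y[on].max()) or (y[~on].min() == y[~on].max()):
                out.append(name)
    return out


def labels_vector(labels: Sequence[ReviewLabel], frame: pd.DataFrame) -> np.ndarray:
    """Align review labels to a flags frame by procedure_id -> 0/1 outcome."""
    lut = {l.procedure_id: int(l.infection) for l in labels}
    missing = [p for p in frame["procedure_id"] if p not in lut]
    if missing:
        raise ValueError(
            f"{len(missing)} procedures lack labels (first: {missing[:3]})")
    return np.array([lut[p] for p in frame["procedure_id"]], dtype=float)


def _firth_fit(X: np.ndarray, y: np.ndarray, tol: float, maxiter: int):
    """Firth bias-reduced logistic regression (Jeffreys-prior penalty).

    Newton iterations on the modified score U*(b) = X'(y - p + h(1/2 - p)),
    h the hat-matrix diagonal.  Always has a finite maximizer, so it is the
    recommended escape hatch under (near-)separation.
    """
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    it = 0
    last_pll = -np.inf
    for it in range(1, maxiter + 1):
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-12, None)
        XW = X * w[:, None]
        info = X.T @ XW
        info_inv = np.linalg.inv(info)
        # hat diagonal of W^(1/2) X (X'WX)^-1 X' W^(1/2)
        h = np.einsum("ij,jk,ik->i", X, info_inv, XW)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        sign, logdet = np.linalg.slogdet(info)
        pll = (y * np.log(np.clip(p, 1e-300, None))
               + (1 - y) * np.log(np.clip(1 - p, 1e-300, None))).sum() + 0.5 * logdet
        if np.max(np.abs(step)) < tol or abs(pll - last_pll) < tol:
            converged = True
            break
        last_pll = pll
    eta = X @ beta
    p = expit(eta)
    ll = (y * np.log(np.clip(p, 1e-300, None))
          + (1 - y) * np.log(np.clip(1 - p, 1e-300, None))).sum()
    w = np.clip(p * (1 - p), 1e-12, None)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, np.sqrt(np.diag(cov)), ll, it, converged


def fit(flags: pd.DataFrame,
        labels: Union[Sequence[ReviewLabel], np.ndarray, Sequence[int]],
        covariates: Sequence[str] = DEFAULT_COVARIATES,
        threshold: float = DEFAULT_THRESHOLD,
        firth: bool = False,
        tol: float = 1e-8,
        maxiter: int = 100) -> TriageModel:
    """Maximum-likelihood logistic fit of infection status on the flags.

    ``labels`` may be ReviewLabels (aligned by procedure_id) or a 0/1
    vector aligned with the frame rows.  Requires at least one positive
    and one negative outcome.  Under complete or quasi-separation the
    plain MLE raises :class:`SeparationError` naming the separating
    covariate(s); refit with ``firth=True`` in that situation.
    """
    if isinstance(labels, (list, tuple)) and labels and isinstance(labels[0], ReviewLabel):
        y = labels_vector(labels, flags)
    else:
        y = np.asarray(labels, dtype=float)
    if len(y) != len(flags):
        raise ValueError("labels and flags length mismatch")
    if y.min() == y.max():
        raise ValueError("need at least one positive and one negative label")

    Xdf = design_matrix(flags, covariates)
    X = np.column_stack([np.ones(len(Xdf)), Xdf.to_numpy()])
    names = ["intercept"] + list(covariates)

    if firth:
        params, bse, llf, niter, converged = _firth_fit(X, y, tol, maxiter)
        method = "firth"
        if not converged:
            raise ConvergenceError(
                f"Firth fit did not converge in {maxiter} iterations")
    else:
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            import warnings

            from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
            with warnings.catch_warnings():
                # converted to SeparationError below; the warning is noise
                warnings.simplefilter("ignore", PerfectSeparationWarning)
                res = model.fit(maxiter=maxiter, tol=tol)
        except Exception as e:  # statsmodels PerfectSeparationError etc.
            seps = _separating_covariates(Xdf.to_numpy(), y, covariates)
            raise SeparationError(
                "logistic MLE diverged (separation); separating covariate(s): "
                f"{seps or 'not identified'}; consider firth=True") from e
        params, bse = np.asarray(res.params), np.asarray(res.bse)
        llf = float(res.llf)
        niter = len(res.fit_history.get("deviance", [])) if hasattr(res, "fit_history") else maxiter
        converged = bool(getattr(res, "converged", True))
        method = "irls"
        if np.max(np.abs(params)) > 30:
            seps = _separating_covariates(Xdf.to_numpy(), y, covariates)
            raise SeparationError(
                "logistic MLE diverged (separation); separating covariate(s): "
                f"{seps or 'not identified'}; consider firth=True")
        if not converged:
            raise ConvergenceError(
                f"IRLS did not converge in {maxiter} iterations "
                f"(deviance trace: {res.fit_history.get('deviance', [])[-5:]})")

    probs = expit(X @ params)
    c_stat = mann_whitney_auc(probs, y.astype(int))
    z = 1.959963984540054  # normal 97.5% quantile
    with np.errstate(over="ignore"):  # huge SEs give inf CI bounds, not errors
        exp_params = np.exp(params)
        ci_lo, ci_hi = np.exp(params - z * bse), np.exp(params + z * bse)
    or_table = pd.DataFrame({
        "covariate": names,
        "coefficient": params,
        "se": bse,
        "odds_ratio": exp_params,
        "or_ci_low": ci_lo,
        "or_ci_high": ci_hi,
    })
    return TriageModel(
        covariates=tuple(covariates),
        coefficients={c: float(b) for c, b in zip(covariates, params[1:])},
        intercept=float(params[0]),
        threshold=threshold,
        diagnostics=FitDiagnostics(converged=converged, iterations=niter,
                                   loglik=llf, c_statistic=c_stat,
                                   method=method),
        or_table=or_table,
        fitted_on={"n": int(len(y)), "positives": int(y.sum())},
    )


def predict(model: TriageModel,
            flags: Union[pd.DataFrame, FlagVector, Mapping]) -> Union[np.ndarray, float]:
    """Predicted infection probability: inverse-logit of the linear
    predictor.  A single FlagVector/dict yields a scalar."""
    scalar = isinstance(flags, (FlagVector, Mapping)) and not isinstance(flags, pd.DataFrame)
    X = design_matrix(flags, model.covariates)
    probs = expit(model.linear_predictor(X))
    return float(probs[0]) if scalar else probs


def predict_frame(model: TriageModel, flags: pd.DataFrame) -> pd.DataFrame:
    """Per-procedure probabilities with the threshold applied."""
    probs = predict(model, flags)
    return pd.DataFrame({
        "procedure_id": flags["procedure_id"].to_numpy(),
        "probability": probs,
        "above_threshold": probs >= model.threshold,
    })


def triage(results: pd.DataFrame,
           threshold: float = DEFAULT_THRESHOLD,
           above_fraction: float = 0.8,
           below_fraction: float = 0.01,
           seed: int = 0) -> pd.DataFrame:
    """Draw the manual-review queue by seeded stratified random sampling.

    ``results`` needs columns ``procedure_id`` and ``probability``.  Within
    the above-threshold stratum (probability >= threshold) a fraction
    ``above_fraction`` of cases is sampled without replacement; within the
    below-threshold stratum, ``below_fraction`` (a safety check that the
    model is not missing true infections).  Sample sizes are
    round(fraction * stratum size); identical seeds give identical queues.
    """
    if not (0 <= above_fraction <= 1 and 0 <= below_fraction <= 1):
        raise ValueError("sampling fractions must lie in [0, 1]")
    out = results.sort_values("procedure_id", kind="mergesort").reset_index(drop=True).copy()
    out["above_threshold"] = out["probability"] >= threshold
    out["selected_for_review"] = False
    rng = np.random.default_rng(seed)
    for above, frac in ((True, above_fraction), (False, below_fraction)):
        idx = out.index[out["above_threshold"] == above].to_numpy()
        k = int(round(frac * len(idx)))
        if k > 0:
            chosen = rng.choice(idx, size=k, replace=False)
            out.loc[chosen, "selected_for_review"] = True
    return out
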