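"""Validation statistics for the triage algorithm.

All accuracy metrics are computed over *reviewed* cases only (partial
verification): only a sample of procedures receives the reference-standard
manual review, and no verification-bias correction is applied, so
sensitivity and specificity should be read as conditional on the review
sampling design.  Point estimates carry Clopper-Pearson exact binomial 95%
confidence intervals.  AUC is the Mann-Whitney concordance probability with
midrank tie handling (identical to the C statistic of a fitted logistic
model evaluated on its own predictions); ROC curve points are taken at
every distinct threshold.  Displayed percentages use half-up rounding to
one decimal place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

from ciedwatch.emr import ReviewLabel

DEFAULT_BAND_EDGES: tuple[float, ...] = (0.0, 0.01, 0.03, 0.10, 0.50, 1.0)


def pct(x: float, dp: int = 1) -> float:
    """Percentage with half-up rounding (the convention of clinical tables:
    41.35 -> 41.4, not banker's 41.3)."""
    if x != x:  # NaN
        return x
    q = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(100.0 * x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class Proportion:
    """A binomial proportion with its exact 95% CI; undefined (None) when
    the denominator is zero."""

    numerator: int
    denominator: int
    value: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def __post_init__(self):
        if self.denominator > 0:
            self.value = self.numerator / self.denominator
            lo, hi = proportion_confint(self.numerator, self.denominator,
                                        alpha=0.05, method="beta")
            self.ci_low, self.ci_high = float(lo), float(hi)

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    ppv: Proportion = field(init=False)
    sensitivity: Proportion = field(init=False)
    specificity: Proportion = field(init=False)

    def __post_init__(self):
        self.ppv = Proportion(self.tp, self.tp + self.fp)
        self.sensitivity = Proportion(self.tp, self.tp + self.fn)
        self.specificity = Proportion(self.tn, self.tn + self.fp)

    @property
    def reviewed(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("ppv", "sensitivity", "specificity"):
            p: Proportion = getattr(self, name)
            rows.append({
                "metric": name,
                "numerator": p.numerator, "denominator": p.denominator,
                "value_pct": pct(p.value) if p.defined else float("nan"),
                "ci_low_pct": pct(p.ci_low) if p.defined else float("nan"),
                "ci_high_pct": pct(p.ci_high) if p.defined else float("nan"),
            })
        return pd.DataFrame(rows)


def metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> ConfusionMetrics:
    """Confusion metrics straight from review counts."""
    return ConfusionMetrics(tp=tp, fp=fp, fn=fn, tn=tn)


def confusion_metrics(labels: Sequence[ReviewLabel],
                      triage: pd.DataFrame,
                      threshold: Optional[float] = None) -> ConfusionMetrics:
    """Confusion metrics over the reviewed cases of a triage run.

    ``triage`` is the frame produced by :func:`ciedwatch.triage.triage`
    (columns procedure_id, probability, above_threshold,
    selected_for_review).  Only labels marked reviewed AND procedures
    selected for review enter the table.  Passing ``threshold`` recomputes
    above_threshold from the probabilities instead of trusting the column.
    """
    lut = {l.procedure_id: l for l in labels if l.reviewed}
    tp = fp = fn = tn = 0
    for row in triage.itertuples(index=False):
        if not getattr(row, "selected_for_review", True):
            continue
        label = lut.get(row.procedure_id)
        if label is None:
            continue
        above = (row.probability >= threshold if threshold is not None
                 else bool(row.above_threshold))
        if above and label.infection:
            tp += 1
        elif above:
            fp += 1
        elif label.infection:
            fn += 1
        else:
            tn += 1
    return ConfusionMetrics(tp=tp, fp=fp, fn=fn, tn=tn)


def _band_label(lo: float, hi: float, last: bool) -> str:
    def f(x: float) -> str:
        p = 100 * x
        return f"{p:g}%"
    return f"{f(lo)}-{f(hi)}" if last else f"{f(lo)}-<{f(hi)}"


def band_table(probabilities: Sequence[float],
               reviewed: Sequence[bool],
               infected: Sequence[bool],
               band_edges: Sequence[float] = DEFAULT_BAND_EDGES) -> pd.DataFrame:
    """Distribution of procedures by predicted-probability band, with the
    reviewed count, true infections, and PPV among reviewed per band.

    Bands are [lo, hi) except the last, which is closed.  ``infected`` is
    only consulted where ``reviewed`` is true.
    """
    edges = list(band_edges)
    if len(edges) < 2 or any(lo >= hi for lo, hi in zip(edges, edges[1:])):
        raise ValueError("band_edges must be strictly increasing")
    p = np.asarray(probabilities, dtype=float)
    rev = np.asarray(reviewed, dtype=bool)
    inf = np.asarray(infected, dtype=bool)
    n = len(p)
    rows = []
    for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
        last = i == len(edges) - 2
        mask = (p >= lo) & ((p <= hi) if last else (p < hi))
        n_band = int(mask.sum())
        n_rev = int((mask & rev).sum())
        n_inf = int((mask & rev & inf).sum())
        rows.append({
            "band": _band_label(lo, hi, last),
            "cohort_n": n_band,
            "cohort_pct": pct(n_band / n) if n else float("nan"),
            "reviewed_n": n_rev,
            "infections_n": n_inf,
            "ppv_pct": pct(n_inf / n_rev) if n_rev else float("nan"),
        })
    return pd.DataFrame(rows)


def band_arrays_from_counts(cohort_counts: Sequence[int],
                            reviewed_counts: Sequence[int],
                            infection_counts: Sequence[int],
                            band_edges: Sequence[float] = DEFAULT_BAND_EDGES,
                            ) -> tuple[list[float], list[bool], list[bool]]:
    """Reconstruct per-case (probability, reviewed, infected) arrays from a
    published probability-band summary, placing each band's cases at the
    band midpoint.  Lets the band/confusion machinery re-derive summary
    statistics from printed tables."""
    edges = list(band_edges)
    if not (len(edges) - 1 == len(cohort_counts) == len(reviewed_counts)
            == len(infection_counts)):
        raise ValueError("count vectors must have one entry per band")
    probs: list[float] = []
    reviewed: list[bool] = []
    infected: list[bool] = []
    for (lo, hi), n, n_rev, n_inf in zip(zip(edges, edges[1:]), cohort_counts,
                                         reviewed_counts, infection_counts):
        if not (n >= n_rev >= n_inf >= 0):
            raise ValueError("need cohort >= reviewed >= infections per band")
        mid = (lo + hi) / 2
        probs += [mid] * n
        reviewed += [True] * n_rev + [False] * (n - n_rev)
        infected += [True] * n_inf + [False] * (n - n_inf)
    return probs, reviewed, infected


def mann_whitney_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the Mann-Whitney concordance probability with midranks.

    Equals P(score_pos > score_neg) + 0.5 P(tie) for a random
    positive/negative pair; ties get half credit.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires at least one positive and one negative")
    ranks = rankdata(s)  # midranks
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_auc(probabilities: Sequence[float],
            labels: Sequence[int]) -> tuple[pd.DataFrame, float]:
    """(ROC curve points, AUC).  Curve points at every distinct threshold."""
    y = np.asarray(labels).astype(int)
    fpr, tpr, thresh = _sk_roc_curve(y, np.asarray(probabilities, dtype=float),
                                     drop_intermediate=False)
    curve = pd.DataFrame({"threshold": thresh, "fpr": fpr, "tpr": tpr})
    return curve, mann_whitney_auc(probabilities, y)


def cohen_kappa(rater_a: Sequence, rater_b: Sequence) -> float:
    """Cohen's kappa for two raters over the same cases.

    Degenerate convention: when both raters assign one identical constant
    label (chance agreement p_e = 1) kappa is defined as 1.0, since the
    raters agree everywhere.
    """
    a = np.asarray(rater_a)
    b = np.asarray(rater_b)
    if a.shape != b.shape:
        raise ValueError("rater label vectors differ in length")
    if len(a) == 0:
        raise ValueError("no cases")
    cats = np.unique(np.concatenate([a, b]))
    po = float(np.mean(a == b))
    pe = float(sum(np.mean(a == c) * np.mean(b == c) for c in cats))
    if pe >= 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def infection_summary(labels: Sequence[ReviewLabel]) -> pd.DataFrame:
    """Counts, percentages, and onset timing by infection type.

    Percentages are of all true infections.  Onset mean/SD are over labels
    with a recorded onset day; SD uses the n-1 denominator and is NaN for
    a single case (documented convention).
    """
    infected = [l for l in labels if l.infection]
    rows = []
    for itype in ("pocket", "endocarditis_or_lead", "cellulitis_only"):
        grp = [l for l in infected if l.infection_type == itype]
        onsets = [l.onset_day for l in grp if l.onset_day is not None]
        rows.append({
            "infection_type": itype,
            "count": len(grp),
            "percent": pct(len(grp) / len(infected)) if infected else float("nan"),
            "onset_mean_d": float(np.mean(onsets)) if onsets else float("nan"),
            "onset_sd_d": float(np.std(onsets, ddof=1)) if len(onsets) > 1 else float("nan"),
        })
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Bundle of every validation statistic for one triage run."""

    metrics: ConfusionMetrics
    auc: float
    c_statistic: Optional[float]
    band_table: pd.DataFrame
    roc_curve: pd.DataFrame
    kappa: Optional[float] = None
    infection_summary: Optional[pd.DataFrame] = None

    @staticmethod
    def _records(df: pd.DataFrame) -> list[dict]:
        recs = df.to_dict("records")
        for r in recs:
            for k, v in r.items():
                if isinstance(v, float) and math.isnan(v):
                    r[k] = None
        return recs

    def to_dict(self) -> dict:
        m = self.metrics

        def prop(p: Proportion):
            if not p.defined:
                return {"numerator": p.numerator, "denominator": p.denominator,
                        "value_pct": None, "ci_pct": None}
            return {"numerator": p.numerator, "denominator": p.denominator,
                    "value_pct": pct(p.value),
                    "ci_pct": [pct(p.ci_low), pct(p.ci_high)]}

        out = {
            "counts": {"tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn,
                       "reviewed": m.reviewed},
            "ppv": prop(m.ppv),
            "sensitivity": prop(m.sensitivity),
            "specificity": prop(m.specificity),
            "auc": None if self.auc is None or math.isnan(self.auc) else round(self.auc, 4),
            "c_statistic": (None if self.c_statistic is None
                            else round(self.c_statistic, 4)),
            "band_table": self._records(self.band_table),
            "kappa": self.kappa,
        }
        if self.infection_summary is not None:
            out["infection_summary"] = self._records(self.infection_summary)
        return out


def evaluate(labels: Sequence[ReviewLabel],
             triage_frame: pd.DataFrame,
             threshold: Optional[float] = None,
             c_statistic: Optional[float] = None,
             band_edges: Sequence[float] = DEFAULT_BAND_EDGES) -> EvalReport:
    """Full validation report for a triage run against review labels."""
    metrics = confusion_metrics(labels, triage_frame, threshold)
    lut = {l.procedure_id: l for l in labels if l.reviewed}
    reviewed_mask = [
        bool(row.selected_for_review) and row.procedure_id in lut
        for row in triage_frame.itertuples(index=False)
    ]
    infected_mask = [
        row.procedure_id in lut and lut[row.procedure_id].infection
        for row in triage_frame.itertuples(index=False)
    ]
    bands = band_table(triage_frame["probability"], reviewed_mask,
                       infected_mask, band_edges)
    rev = triage_frame.loc[reviewed_mask]
    y = [int(lut[p].infection) for p in rev["procedure_id"]]
    if len(set(y)) > 1:
        curve, auc = roc_auc(rev["probability"], y)
    else:
        curve, auc = pd.DataFrame(columns=["threshold", "fpr", "tpr"]), float("nan")
    summary = infection_summary([l for l in labels if l.reviewed])
    return EvalReport(metrics=metrics, auc=auc, c_statistic=c_statistic,
                      band_table=bands, roc_curve=curve,
                      infection_summary=summary)
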