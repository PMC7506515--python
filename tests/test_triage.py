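"""Logistic triage model: fit correctness against independent oracles,
prediction arithmetic, and review-queue sampling."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from ciedwatch.synth import simulate_logistic
from ciedwatch.triage import (
    DEFAULT_COVARIATES,
    SeparationError,
    TriageModel,
    design_matrix,
    fit,
    predict,
    predict_frame,
    triage,
)


def grid_search_mle(X: np.ndarray, y: np.ndarray,
                    rounds: int = 6, span: float = 4.0,
                    steps: int = 21) -> np.ndarray:
    """Independent oracle: maximize the Bernoulli log-likelihood by iterated
    grid refinement over (intercept, b1, b2) — no IRLS involved."""
    Xd = np.column_stack([np.ones(len(X)), X])
    center = np.zeros(Xd.shape[1])
    for _ in range(rounds):
        axes = [np.linspace(c - span, c + span, steps) for c in center]
        grids = np.meshgrid(*axes, indexing="ij")
        B = np.stack([g.ravel() for g in grids], axis=1)
        eta = B @ Xd.T
        ll = (y * eta - np.logaddexp(0.0, eta)).sum(axis=1)
        center = B[np.argmax(ll)]
        span /= 5.0
    return center


def test_intercept_only_fit_is_logit_of_prevalence():
    y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], dtype=float)
    frame = pd.DataFrame({"procedure_id": [f"p{i}" for i in range(10)]})
    model = fit(frame, y, covariates=())
    assert math.isclose(model.intercept, math.log(3 / 7), abs_tol=1e-6)


def test_fit_matches_grid_search_oracle_on_tiny_instance():
    x1 = np.array([0, 0, 0, 1, 1, 1, 0, 0, 1, 1, 0, 1], dtype=float)
    x2 = np.array([0, 1, 0, 0, 1, 1, 1, 0, 0, 1, 1, 0], dtype=float)
    y = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 1, 0, 0], dtype=float)
    frame = pd.DataFrame({"x1": x1, "x2": x2})
    model = fit(frame, y, covariates=("x1", "x2"))
    oracle = grid_search_mle(np.column_stack([x1, x2]), y)
    fitted = np.array([model.intercept, model.coefficients["x1"],
                       model.coefficients["x2"]])
    assert np.allclose(fitted, oracle, atol=1e-3)


def test_planted_coefficients_recovered_within_two_se():
    planted = {"a": 1.2, "b": -0.8, "c": 0.5}
    X, y = simulate_logistic(
        n=5000, intercept=-1.0, beta=planted,
        covariate_probs={"a": 0.4, "b": 0.3, "c": 0.5}, seed=20)
    model = fit(X, y, covariates=("a", "b", "c"))
    se = dict(zip(model.or_table["covariate"], model.or_table["se"]))
    for name, b in planted.items():
        assert abs(model.coefficients[name] - b) <= 2 * se[name], name
    assert abs(model.intercept + 1.0) <= 2 * se["intercept"]


def test_fit_requires_both_outcome_classes():
    frame = pd.DataFrame({"x": [0.0, 1.0, 0.0]})
    with pytest.raises(ValueError):
        fit(frame, np.ones(3), covariates=("x",))


def test_separation_raises_with_covariate_named():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, size=60).astype(float)
    frame = pd.DataFrame({"clean": rng.integers(0, 2, 60).astype(float),
                          "leaky": y})
    with pytest.raises(SeparationError, match="leaky"):
        fit(frame, y, covariates=("clean", "leaky"))


def test_firth_fit_is_finite_under_separation():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, size=60).astype(float)
    frame = pd.DataFrame({"leaky": y,
                          "clean": rng.integers(0, 2, 60).astype(float)})
    model = fit(frame, y, covariates=("leaky", "clean"), firth=True)
    assert all(np.isfinite(list(model.coefficients.values())))
    assert model.diagnostics.method == "firth"


def test_fit_invariant_to_row_permutation():
    X, y = simulate_logistic(n=800, intercept=-0.5, beta={"a": 0.9, "b": -0.4},
                             covariate_probs={"a": 0.5, "b": 0.4}, seed=7)
    m1 = fit(X, y, covariates=("a", "b"))
    perm = np.random.default_rng(3).permutation(len(y))
    m2 = fit(X.iloc[perm].reset_index(drop=True), y[perm], covariates=("a", "b"))
    assert math.isclose(m1.intercept, m2.intercept, abs_tol=1e-8)
    for c in ("a", "b"):
        assert math.isclose(m1.coefficients[c], m2.coefficients[c], abs_tol=1e-8)


def toy_model(**coef) -> TriageModel:
    return TriageModel(covariates=tuple(coef), coefficients=dict(coef),
                       intercept=-2.0, threshold=0.10)


class TestPredict:
    def test_all_zero_covariates_gives_inverse_logit_of_intercept(self):
        model = toy_model(a=1.0, b=2.0)
        p = predict(model, {"a": 0, "b": 0})
        assert math.isclose(p, expit(-2.0), abs_tol=1e-12)

    def test_hand_computed_probability_to_1e_12(self):
        model = toy_model(a=0.7, b=-1.3)
        p = predict(model, {"a": 1, "b": 1})
        assert math.isclose(p, expit(-2.0 + 0.7 - 1.3), abs_tol=1e-12)

    def test_positive_coefficient_strictly_increases_probability(self):
        model = toy_model(icd=3.0)
        assert predict(model, {"icd": 1}) > predict(model, {"icd": 0})

    def test_missing_covariate_error_names_it(self):
        model = toy_model(note_flag=1.0)
        with pytest.raises(ValueError, match="note_flag"):
            predict(model, {"other": 1})

    def test_round_trip_through_model_json(self, tmp_path):
        model = toy_model(a=0.123456789, b=-9.87)
        model.to_json(tmp_path / "model.json")
        back = TriageModel.from_json(tmp_path / "model.json")
        assert back.coefficients == model.coefficients
        assert back.threshold == model.threshold
        assert predict(back, {"a": 1, "b": 0}) == predict(model, {"a": 1, "b": 0})

    def test_antibiotic_class_expands_to_indicators(self):
        X = design_matrix(pd.DataFrame({"antibiotic_class":
                                        ["none", "staph_directed", "non_staph"]}),
                          ("antibiotic_staph_directed", "antibiotic_non_staph"))
        assert X["antibiotic_staph_directed"].tolist() == [0.0, 1.0, 0.0]
        assert X["antibiotic_non_staph"].tolist() == [0.0, 0.0, 1.0]


def preds(probs) -> pd.DataFrame:
    return pd.DataFrame({"procedure_id": [f"p{i:03d}" for i in range(len(probs))],
                         "probability": probs})


class TestTriage:
    def test_full_above_none_below_is_exactly_the_flagged_set(self):
        frame = preds([0.05, 0.2, 0.5, 0.01, 0.15])
        queue = triage(frame, threshold=0.10, above_fraction=1.0,
                       below_fraction=0.0, seed=1)
        sel = set(queue.loc[queue["selected_for_review"], "procedure_id"])
        assert sel == {"p001", "p002", "p004"}

    def test_same_seed_gives_identical_queue(self):
        rng = np.random.default_rng(5)
        frame = preds(rng.random(500))
        q1 = triage(frame, seed=42)
        q2 = triage(frame, seed=42)
        assert q1.equals(q2)
        q3 = triage(frame, seed=43)
        assert not q1["selected_for_review"].equals(q3["selected_for_review"])

    def test_stratum_sample_sizes_are_rounded_fractions(self):
        rng = np.random.default_rng(8)
        frame = preds(rng.random(2000))
        queue = triage(frame, threshold=0.10, above_fraction=0.8,
                       below_fraction=0.01, seed=0)
        above = queue["above_threshold"]
        n_above, n_below = int(above.sum()), int((~above).sum())
        assert queue.loc[above, "selected_for_review"].sum() == round(0.8 * n_above)
        assert queue.loc[~above, "selected_for_review"].sum() == round(0.01 * n_below)

    def test_raising_threshold_never_increases_flagged_count(self):
        rng = np.random.default_rng(2)
        frame = preds(rng.random(300))
        counts = [triage(frame, threshold=t, seed=0)["above_threshold"].sum()
                  for t in (0.05, 0.10, 0.30, 0.60)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            triage(preds([0.5]), above_fraction=1.5)


def test_predict_frame_applies_threshold():
    model = TriageModel(covariates=("a",), coefficients={"a": 5.0},
                        intercept=-2.0, threshold=0.5)
    frame = pd.DataFrame({"procedure_id": ["x", "y"], "a": [0.0, 1.0]})
    out = predict_frame(model, frame)
    # expit(-2) = 0.12 stays below 0.5; expit(3) = 0.95 crosses it
    assert out["above_threshold"].tolist() == [False, True]


def test_default_covariates_cover_the_final_model_terms():
    # the covariate surface the triage model must support
    assert set(DEFAULT_COVARIATES) == {
        "died_90d", "congestive_heart_failure",
        "solid_tumor_without_metastasis", "icd_cied_infection", "icd_ssi",
        "antibiotic_staph_directed", "antibiotic_non_staph",
        "micro_cardiac_pos", "note_infection_post", "note_infection_pre"}
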