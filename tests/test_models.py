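"""Design matrix assembly and the three regression stages."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from rxnet import states as st
from rxnet._mixed import fit_cox_frailty, fit_logit_gh
from rxnet.models import (
    ModelData,
    build_design_matrix,
    fit_cox_obs,
    fit_multinomial_transition,
    fit_opioid_logit,
    predict_multinomial,
)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def toy_metrics():
    return pd.DataFrame(
        {
            "closeness": [0.5, -0.2, 1.1, 0.0],
            "clustering": [0.1, 0.9, -0.4, 0.2],
            "volume": [1.2, 0.3, -0.5, 0.0],
            "specialty": ["Primary Care", "Emergency Medicine", "Psychiatry", "Other"],
            "in_lcc": [True, True, True, False],
        },
        index=pd.Index(["d1", "d2", "d3", "d4"], name="physician_id"),
    )


def toy_patients():
    return pd.DataFrame(
        {
            "patient_id": ["p1", "p2", "p3"],
            "age": [70, 80, 75],
            "sex": ["F", "M", "F"],
            "race": ["White", "Black", "Other"],
        }
    )


def toy_transitions(docs=("d1", "d2", "d3")):
    rows = []
    for i, doc in enumerate(docs):
        rows.append(
            {"patient_id": f"p{i % 3 + 1}", "from_mask": 0, "to_mask": st.O,
             "drug_count_from": 0, "drug_count_to": 1, "date": 10 * i,
             "responsible_physician_id": doc}
        )
    return pd.DataFrame(rows)


def test_specialty_dummies_use_primary_care_reference():
    data = build_design_matrix(toy_transitions(), toy_metrics(), toy_patients())
    em_row = data.frame[data.frame["responsible_physician_id"] == "d2"].iloc[0]
    assert (em_row["spec_emergency"], em_row["spec_neurology"],
            em_row["spec_psychiatry"], em_row["spec_other"]) == (1, 0, 0, 0)
    pc_row = data.frame[data.frame["responsible_physician_id"] == "d1"].iloc[0]
    assert pc_row[["spec_emergency", "spec_neurology", "spec_psychiatry",
                   "spec_other"]].sum() == 0
    # no reference-category column exists
    assert "spec_primary_care" not in data.frame.columns


def test_interaction_column_is_product_of_standardized_columns():
    data = build_design_matrix(
        toy_transitions(), toy_metrics(), toy_patients(), interaction=True
    )
    assert "closeness_x_volume" in data.predictors
    np.testing.assert_allclose(
        data.frame["closeness_x_volume"], data.frame["closeness"] * data.frame["volume"]
    )


def test_non_lcc_records_are_excluded_and_counted():
    data = build_design_matrix(
        toy_transitions(docs=("d1", "d4", "d2")), toy_metrics(), toy_patients()
    )
    assert data.n_excluded == 1
    assert len(data.frame) == 2


def test_row_conservation_on_simulated_cohort(small_cohort):
    from rxnet.pipeline import _standardized_model_metrics

    res = st.analyze_cohort(small_cohort["fills"], 365)
    trans = st.transitions_to_frame(res["transitions"])
    mm = _standardized_model_metrics(small_cohort["metrics"])
    data = build_design_matrix(trans, mm, small_cohort["patients"])
    assert len(data.frame) + data.n_excluded == len(trans)


def test_missing_patient_raises():
    with pytest.raises(KeyError, match="patients missing"):
        build_design_matrix(
            toy_transitions(), toy_metrics(), toy_patients().iloc[:1]
        )


# ---------------------------------------------------------------------------
# multinomial stage
# ---------------------------------------------------------------------------

def _simulated_model_data(n=600, seed=0, betas=None, n_cat=3):
    """Direct multinomial-logit draws onto a ModelData frame."""
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    betas = betas or {"cat2": (0.4, -0.6, 0.3), "cat3": (-0.8, 0.5, -0.2)}
    eta2 = betas["cat2"][0] + betas["cat2"][1] * x1 + betas["cat2"][2] * x2
    eta3 = betas["cat3"][0] + betas["cat3"][1] * x1 + betas["cat3"][2] * x2
    if n_cat == 2:
        eta3 = np.full(n, -np.inf)
    p = np.exp(np.column_stack([np.zeros(n), eta2, eta3]))
    p /= p.sum(axis=1, keepdims=True)
    y = np.array([rng.choice(3, p=pi) for pi in p]) + 1
    frame = pd.DataFrame(
        {
            "drug_count_from": 0,
            "drug_count_to": y,
            "closeness": x1,
            "clustering": x2,
            "patient_id": [f"p{i}" for i in range(n)],
            "responsible_physician_id": [f"d{i % 40}" for i in range(n)],
        }
    )
    return ModelData(frame=frame, predictors=["closeness", "clustering"])


def _direct_mnl_loglik(params, X, y, n_others):
    B = params.reshape(n_others, X.shape[1])
    eta = X @ B.T
    m = np.maximum(eta.max(axis=1), 0)
    logden = m + np.log(np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1))
    pick = np.where(y > 0, np.take_along_axis(eta, np.maximum(y - 1, 0)[:, None], 1).ravel(), 0.0)
    return float((pick - logden).sum())


def test_multinomial_matches_independent_optimizer():
    data = _simulated_model_data(n=200, seed=1)
    fit = fit_multinomial_transition(data, start_count=0)
    df = data.frame
    X = np.column_stack([np.ones(len(df)), df["closeness"], df["clustering"]])
    y = df["drug_count_to"].to_numpy() - 1
    res = minimize(
        lambda b: -_direct_mnl_loglik(b, X, y, 2),
        np.zeros(6), method="BFGS", options={"gtol": 1e-10},
    )
    np.testing.assert_allclose(fit.params.to_numpy(), res.x, rtol=1e-4, atol=1e-5)
    assert fit.loglik == pytest.approx(-res.fun, rel=1e-8)


def test_multinomial_predicted_probabilities_sum_to_one():
    data = _simulated_model_data(n=400, seed=2)
    fit = fit_multinomial_transition(data, start_count=0)
    probs = predict_multinomial(fit, data, start_count=0)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)
    assert (probs >= 0).all()


def test_multinomial_invariant_to_row_order_and_id_relabeling():
    data = _simulated_model_data(n=300, seed=3)
    fit1 = fit_multinomial_transition(data, start_count=0)
    shuffled = data.frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
    shuffled["patient_id"] = "zz_" + shuffled["patient_id"]
    fit2 = fit_multinomial_transition(
        ModelData(frame=shuffled, predictors=data.predictors), start_count=0
    )
    np.testing.assert_allclose(fit1.params, fit2.params, atol=1e-8)


def test_multinomial_requires_enough_rows_per_category():
    data = _simulated_model_data(n=30, seed=4)
    with pytest.raises(ValueError):
        fit_multinomial_transition(data, start_count=0, min_rows_per_category=25)


def test_multinomial_laplace_close_to_fixed_effects_when_no_clustering():
    data = _simulated_model_data(n=500, seed=5)
    fixed = fit_multinomial_transition(data, start_count=0)
    mixed = fit_multinomial_transition(data, start_count=0, random_effects=True)
    assert mixed.converged
    # independent rows: variance components collapse, estimates agree
    assert mixed.vc["sigma2_patient"] < 0.05
    assert mixed.vc["tau2_physician"] < 0.05
    np.testing.assert_allclose(mixed.params, fixed.params, atol=0.05)


def test_model_fit_invariants():
    data = _simulated_model_data(n=300, seed=6)
    fit = fit_multinomial_transition(data, start_count=0)
    assert ((fit.conf_low <= fit.params) & (fit.params <= fit.conf_high)).all()
    np.testing.assert_allclose(fit.exp_params, np.exp(fit.params), atol=1e-10)
    assert fit.aic == pytest.approx(2 * fit.nparams - 2 * fit.loglik, abs=1e-8)


# ---------------------------------------------------------------------------
# opioid logistic stage
# ---------------------------------------------------------------------------

def _logit_frame(n=400, seed=0, beta=(0.0, 0.0), tau=0.0, n_groups=40):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    groups = rng.integers(n_groups, size=n)
    u = rng.normal(0, tau, size=n_groups)
    eta = beta[0] + beta[1] * x + u[groups]
    y = (rng.random(n) < expit(eta)).astype(int)
    frame = pd.DataFrame(
        {
            "from_mask": st.O,
            "to_mask": np.where(y == 1, st.O | st.B, 0),
            "closeness": x,
            "patient_id": [f"p{i}" for i in range(n)],
            "responsible_physician_id": [f"d{g}" for g in groups],
        }
    )
    return ModelData(frame=frame, predictors=["closeness"])


def test_intercept_only_logit_reproduces_empirical_rate():
    data = _logit_frame(n=500, seed=7, beta=(0.7, 0.0))
    frame = data.frame.copy()
    fit = fit_opioid_logit(ModelData(frame=frame, predictors=[]), random_effect=False)
    rate = (frame["to_mask"] != 0).mean()
    assert expit(fit.params["intercept"]) == pytest.approx(rate, abs=1e-6)


def test_logit_requires_events_and_nonevents():
    data = _logit_frame(n=100, seed=8, beta=(9.0, 0.0))
    with pytest.raises(ValueError):
        fit_opioid_logit(data, random_effect=False)


def test_gh_logit_recovers_null_variance_component():
    data = _logit_frame(n=800, seed=9, beta=(-0.4, 0.5), tau=0.0)
    fit = fit_opioid_logit(data, random_effect=True)
    assert fit.vc["tau2_physician"] < 0.05
    assert abs(fit.params["closeness"] - 0.5) < 0.15


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_gh_logit_matches_lme4_glmer(tmp_path):
    """Independent oracle: lme4::glmer on the same random-intercept data."""
    data = _logit_frame(n=600, seed=10, beta=(-0.3, 0.6), tau=0.8, n_groups=60)
    fit = fit_opioid_logit(data, random_effect=True)

    df = data.frame
    csv = tmp_path / "d.csv"
    pd.DataFrame(
        {"y": (df["to_mask"] != 0).astype(int), "x": df["closeness"],
         "g": df["responsible_physician_id"]}
    ).to_csv(csv, index=False)
    rout = tmp_path / "out.csv"
    script = (
        f"d <- read.csv('{csv}');"
        "suppressMessages(library(lme4));"
        "m <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=25);"
        "fe <- fixef(m); tau <- sqrt(unlist(VarCorr(m))[1]);"
        f"write.csv(data.frame(b0=fe[1], b1=fe[2], tau=tau), '{rout}', row.names=FALSE)"
    )
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True,
                   timeout=300)
    ref = pd.read_csv(rout).iloc[0]
    assert fit.params["intercept"] == pytest.approx(ref["b0"], abs=0.02)
    assert fit.params["closeness"] == pytest.approx(ref["b1"], abs=0.02)
    assert np.sqrt(fit.vc["tau2_physician"]) == pytest.approx(ref["tau"], abs=0.05)


# ---------------------------------------------------------------------------
# Cox stage
# ---------------------------------------------------------------------------

def _duration_frame(dur, censored, x, pats=None, docs=None):
    n = len(dur)
    frame = pd.DataFrame(
        {
            "duration_days": dur,
            "censored": censored,
            "closeness": x,
            "patient_id": pats if pats is not None else [f"p{i}" for i in range(n)],
            "responsible_physician_id": docs if docs is not None else [f"d{i % 25}" for i in range(n)],
        }
    )
    return ModelData(frame=frame, predictors=["closeness"])


def test_cox_recovers_two_group_hazard_ratio():
    rng = np.random.default_rng(11)
    n = 2000
    group = np.repeat([0.0, 1.0], n // 2)
    lam = 0.05 * np.exp(np.log(2) * group)
    dur = rng.exponential(1 / lam)
    data = _duration_frame(dur, np.zeros(n, bool), group)
    fit = fit_cox_obs(data)
    assert 1.85 < float(fit.exp_params["closeness"]) < 2.15


def test_cox_with_equal_durations_is_uninformative_but_converges():
    n = 60
    data = _duration_frame(np.full(n, 20.0), np.zeros(n, bool),
                           np.r_[np.zeros(n // 2), np.ones(n // 2)])
    fit = fit_cox_obs(data)
    assert fit.converged
    assert float(fit.exp_params["closeness"]) == pytest.approx(1.0, abs=1e-6)


def test_cox_matches_lifelines_oracle():
    rng = np.random.default_rng(12)
    n = 400
    x = rng.normal(size=n)
    dur = rng.exponential(1 / (0.05 * np.exp(0.4 * x)))
    cens = dur > 60
    dur = np.minimum(dur, 60.0)
    data = _duration_frame(dur, cens, x)
    fit = fit_cox_obs(data)

    from lifelines import CoxPHFitter

    df = pd.DataFrame({"t": dur, "e": (~cens).astype(int), "x": x})
    ll = CoxPHFitter().fit(df, duration_col="t", event_col="e")
    assert fit.params["closeness"] == pytest.approx(
        ll.params_["x"], abs=1e-4
    )


def test_cox_efron_ties_option_runs_and_differs_under_heavy_ties():
    rng = np.random.default_rng(13)
    n = 300
    x = rng.normal(size=n)
    dur = np.ceil(rng.exponential(5 * np.exp(-0.3 * x)))  # integer days: many ties
    data = _duration_frame(dur, np.zeros(n, bool), x)
    breslow = fit_cox_obs(data, ties="breslow")
    efron = fit_cox_obs(data, ties="efron")
    assert breslow.method.endswith("breslow") and efron.method.endswith("efron")
    assert abs(breslow.params["closeness"] - efron.params["closeness"]) < 0.1


def test_cox_frailty_close_to_model1_when_no_clustering():
    rng = np.random.default_rng(14)
    n = 300
    x = rng.normal(size=n)
    dur = rng.exponential(1 / (0.05 * np.exp(0.3 * x)))
    data = _duration_frame(dur, np.zeros(n, bool), x)
    fit2 = fit_cox_obs(data, frailty=True)
    fit1 = fit_cox_obs(data, frailty=False)
    assert fit2.params["closeness"] == pytest.approx(fit1.params["closeness"], abs=0.1)
    assert fit2.vc["sigma2_patient"] < 0.2
    assert fit2.vc["tau2_physician"] < 0.2


def test_cox_frailty_recovers_physician_frailty_signal():
    rng = np.random.default_rng(15)
    n_docs, per_doc = 40, 12
    n = n_docs * per_doc
    docs = np.repeat([f"d{i}" for i in range(n_docs)], per_doc)
    w = np.repeat(rng.normal(0, 0.8, n_docs), per_doc)
    x = rng.normal(size=n)
    dur = rng.exponential(1 / (0.05 * np.exp(0.4 * x + w)))
    data = _duration_frame(dur, np.zeros(n, bool), x, docs=docs)
    fit = fit_cox_obs(data, frailty=True)
    assert fit.converged
    assert fit.vc["tau2_physician"] > 0.1  # detects real clustering
    assert abs(fit.params["closeness"] - 0.4) < 0.15


def test_cox_requires_events():
    data = _duration_frame(np.full(20, 10.0), np.ones(20, bool), np.zeros(20))
    with pytest.raises(ValueError):
        fit_cox_obs(data)


# ---------------------------------------------------------------------------
# AIC and the closeness x volume interaction
# ---------------------------------------------------------------------------

def test_aic_prefers_interaction_when_data_generated_with_it():
    rng = np.random.default_rng(16)
    n = 4000
    clo = rng.normal(size=n)
    vol = rng.normal(size=n)
    eta2 = -0.5 + 0.3 * clo + 0.4 * clo * vol
    eta3 = -1.5 + 0.3 * clo + 0.4 * clo * vol
    p = np.exp(np.column_stack([np.zeros(n), eta2, eta3]))
    p /= p.sum(axis=1, keepdims=True)
    y = np.array([rng.choice(3, p=pi) for pi in p]) + 1
    frame = pd.DataFrame(
        {"drug_count_from": 0, "drug_count_to": y, "closeness": clo, "volume": vol,
         "closeness_x_volume": clo * vol,
         "patient_id": [f"p{i}" for i in range(n)],
         "responsible_physician_id": [f"d{i % 50}" for i in range(n)]}
    )
    with_ix = fit_multinomial_transition(
        ModelData(frame=frame, predictors=["closeness", "volume", "closeness_x_volume"]), 0
    )
    without = fit_multinomial_transition(
        ModelData(frame=frame, predictors=["closeness", "volume"]), 0
    )
    assert with_ix.aic < without.aic + 2
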