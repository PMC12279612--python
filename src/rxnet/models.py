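"""The three regression stages of the transition analysis.

Stage 1 -- a multinomial (mixed) logit for the drug-count transition model:
from a starting count ``u`` the three admissible ending counts form the
outcome, with the lowest count as the reference; from state zero this is
exactly the published contrast of 2-drug and 3-drug prescribing against
1-drug prescribing.

Stage 2 -- a logistic simplification for opioid-focused transitions:
``O -> {OB, OS, OBS}`` (risky) versus ``O -> zero``, with a physician
random intercept (patients average fewer than two such transitions, so
patient clustering is not modeled).

Stage 3 -- Cox proportional hazards for the time to discontinuation of
state OBS, with and without crossed patient/physician frailties.

Predictors throughout: patient age (years), sex, race; the responsible
physician's SD-standardized network measures and annual patient volume;
and specialty dummies with Primary Care as the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from . import _mixed
from . import states as st

__all__ = ["ModelData", "ModelFit", "build_design_matrix",
           "fit_multinomial_transition", "predict_multinomial",
           "fit_opioid_logit", "fit_cox_obs"]

_Z95 = stats.norm.ppf(0.975)

SPECIALTY_DUMMIES = {
    "Emergency Medicine": "spec_emergency",
    "Neurology": "spec_neurology",
    "Psychiatry": "spec_psychiatry",
    "Other": "spec_other",
}


@dataclass
class ModelData:
    """Design-matrix rows for the regression stages.

    ``frame`` has one row per transition (or OBS spell), joined covariates
    and grouping labels; ``predictors`` is the ordered list of covariate
    columns; ``n_excluded`` counts records dropped because the responsible
    physician was outside the largest connected component.
    """

    frame: pd.DataFrame
    predictors: list[str]
    n_excluded: int = 0
    standardization: dict[str, float] = field(default_factory=dict)


@dataclass
class ModelFit:
    """Coefficients with Wald uncertainty, on the log-odds/log-hazard scale."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_low: pd.Series
    conf_high: pd.Series
    scale: str                      # "log-odds" or "log-hazard"
    loglik: float
    aic: float
    nparams: int
    converged: bool
    method: str
    vc: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    @property
    def exp_params(self) -> pd.Series:
        """Odds or hazard ratios, ``exp(coefficient)``."""
        return np.exp(self.params)

    def summary_frame(self) -> pd.DataFrame:
        label = "OR" if self.scale == "log-odds" else "HR"
        return pd.DataFrame(
            {
                "coef": self.params,
                label: self.exp_params,
                "se": self.bse,
                f"{label}_ci_low": np.exp(self.conf_low),
                f"{label}_ci_high": np.exp(self.conf_high),
                "p_value": self.pvalues,
            }
        )


def _wald(params, bse, names, scale, loglik, nparams, converged, method,
          vc=None, extra=None) -> ModelFit:
    params = pd.Series(np.asarray(params, float), index=names)
    bse = pd.Series(np.asarray(bse, float), index=names)
    z = params / bse
    pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names)
    return ModelFit(
        params=params, bse=bse, pvalues=pvals,
        conf_low=params - _Z95 * bse, conf_high=params + _Z95 * bse,
        scale=scale, loglik=float(loglik), aic=2 * nparams - 2 * float(loglik),
        nparams=nparams, converged=converged, method=method,
        vc=vc or {}, extra=extra or {},
    )


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def _usable_predictors(df: pd.DataFrame, predictors: list[str]) -> tuple[list[str], list[str]]:
    """Drop predictors with no variation in this stage's rows.

    A constant column (e.g. a specialty dummy with no such prescriber among
    the stage's responsible physicians) makes the information matrix
    singular; dropping it is equivalent to absorbing it into the intercept.
    """
    kept, dropped = [], []
    for name in predictors:
        v = df[name].to_numpy()
        (kept if v.max() > v.min() else dropped).append(name)
    return kept, dropped


def build_design_matrix(
    transitions: pd.DataFrame,
    metrics_std: pd.DataFrame,
    patients: pd.DataFrame,
    measures: tuple[str, ...] = ("closeness", "clustering"),
    include_volume: bool = True,
    interaction: bool = False,
) -> ModelData:
    """Join transition records to patient and physician covariates.

    ``metrics_std`` must carry SD-standardized measure columns, ``volume``
    (standardized), ``specialty`` and ``in_lcc``; records whose
    responsible physician is outside the LCC are excluded (counted in
    ``n_excluded``).  Specialty dummies use Primary Care as reference.
    The optional interaction column is the product of the standardized
    closeness and volume columns.
    """
    df = transitions.copy()
    df["responsible_physician_id"] = df["responsible_physician_id"].astype(str)
    met = metrics_std.copy()
    met.index = met.index.astype(str)

    in_lcc = met["in_lcc"] if "in_lcc" in met.columns else pd.Series(True, index=met.index)
    ok = df["responsible_physician_id"].map(in_lcc)
    if ok.isna().any():
        missing = df.loc[ok.isna(), "responsible_physician_id"].unique()
        raise KeyError(f"physicians missing from metrics: {list(missing[:5])}")
    n_excluded = int((~ok.astype(bool)).sum())
    df = df[ok.astype(bool)].copy()

    pats = patients.astype({"patient_id": str}).set_index("patient_id")
    unknown = set(df["patient_id"].astype(str)) - set(pats.index)
    if unknown:
        raise KeyError(f"patients missing from roster: {sorted(unknown)[:5]}")

    pid = df["patient_id"].astype(str)
    doc = df["responsible_physician_id"]
    df["age"] = pats["age"].reindex(pid).to_numpy(dtype=float)
    df["female"] = (pats["sex"].reindex(pid) == "F").to_numpy(dtype=float)
    df["race_black"] = (pats["race"].reindex(pid) == "Black").to_numpy(dtype=float)
    df["race_other"] = (pats["race"].reindex(pid) == "Other").to_numpy(dtype=float)

    predictors = ["age", "female", "race_black", "race_other"]
    for m in measures:
        df[m] = met[m].reindex(doc).to_numpy(dtype=float)
        predictors.append(m)
    if include_volume:
        df["volume"] = met["volume"].reindex(doc).to_numpy(dtype=float)
        predictors.append("volume")
    spec = met["specialty"].reindex(doc)
    for name, col in SPECIALTY_DUMMIES.items():
        df[col] = (spec == name).to_numpy(dtype=float)
        predictors.append(col)
    if interaction:
        if "closeness" not in df.columns or "volume" not in df.columns:
            raise ValueError("interaction requires closeness and volume columns")
        df["closeness_x_volume"] = df["closeness"] * df["volume"]
        predictors.append("closeness_x_volume")

    cols = predictors + [c for c in df.columns if c not in predictors]
    bad = df[predictors].isna().any()
    if bad.any():
        raise ValueError(f"missing covariate values in {list(bad[bad].index)}")
    return ModelData(
        frame=df[cols].reset_index(drop=True),
        predictors=predictors,
        n_excluded=n_excluded,
        standardization=dict(metrics_std.attrs.get("standardization_sds", {})),
    )


# ---------------------------------------------------------------------------
# Stage 1: multinomial transition model
# ---------------------------------------------------------------------------

def fit_multinomial_transition(
    data: ModelData,
    start_count: int = 0,
    baseline_outcome: int | None = None,
    random_effects: bool = False,
    min_rows_per_category: int = 10,
) -> ModelFit:
    """Drug-count transition model for one starting state.

    The outcome is the ending drug count among the three admissible
    categories; the reference is ``baseline_outcome`` (default: the lowest
    admissible count, i.e. 1-drug prescribing when starting from zero).
    Without random effects this is a fixed-effects multinomial logit with
    physician-cluster-robust standard errors; with them, crossed normal
    patient/physician intercepts are integrated out by a Laplace
    approximation.  Parameter names are ``"<count>-drug:<predictor>"``.
    """
    df = data.frame[data.frame["drug_count_from"] == start_count]
    counts = df["drug_count_to"].value_counts()
    categories = sorted(counts.index)
    if len(categories) < 2:
        raise ValueError(f"need >= 2 outcome categories, got {categories}")
    if (counts < min_rows_per_category).any():
        small = counts[counts < min_rows_per_category]
        raise ValueError(f"outcome categories with too few rows: {dict(small)}")
    ref = categories[0] if baseline_outcome is None else baseline_outcome
    others = [c for c in categories if c != ref]
    code = {ref: 0, **{c: i + 1 for i, c in enumerate(others)}}
    y = df["drug_count_to"].map(code).to_numpy()

    predictors, dropped = _usable_predictors(df, data.predictors)
    X = sm.add_constant(df[predictors].to_numpy(dtype=float), prepend=True)
    xnames = ["intercept"] + list(predictors)
    names = [f"{c}-drug:{x}" for c in others for x in xnames]

    if not random_effects:
        groups = pd.factorize(df["responsible_physician_id"])[0]
        model = sm.MNLogit(y, X)
        res = model.fit(
            method="newton", maxiter=200, disp=0,
            cov_type="cluster", cov_kwds={"groups": groups},
        )
        params = np.asarray(res.params).T.ravel()  # stack (J-1, p) per category
        bse = np.asarray(res.bse).T.ravel()
        fit = _wald(
            params, bse, names, "log-odds", res.llf, X.shape[1] * len(others),
            bool(res.mle_retvals.get("converged", True)), "MNLogit-cluster",
            extra={"statsmodels": res, "categories": [ref] + others,
                   "dropped_predictors": dropped},
        )
        return fit

    pat = pd.factorize(df["patient_id"])[0]
    phys = pd.factorize(df["responsible_physician_id"])[0]
    mres = _mixed.fit_multinomial_laplace(X, y, pat, phys, n_cat=len(categories))
    return _wald(
        mres.params, mres.bse, names, "log-odds", mres.loglik, mres.nparams,
        mres.converged, mres.method, vc=mres.vc,
        extra={"categories": [ref] + others, "dropped_predictors": dropped},
    )


def predict_multinomial(fit: ModelFit, data: ModelData, start_count: int = 0) -> np.ndarray:
    """Per-row predicted category probabilities from a fixed-effects fit."""
    df = data.frame[data.frame["drug_count_from"] == start_count]
    X = sm.add_constant(df[data.predictors].to_numpy(dtype=float), prepend=True)
    n_others = len(fit.params) // X.shape[1]
    B = fit.params.to_numpy().reshape(n_others, X.shape[1])
    eta = X @ B.T
    shift = np.maximum(eta.max(axis=1), 0.0)
    e = np.exp(eta - shift[:, None])
    base = np.exp(-shift)
    den = base + e.sum(axis=1)
    return np.column_stack([base[:, None], e]) / den[:, None]


# ---------------------------------------------------------------------------
# Stage 2: opioid-focused logistic
# ---------------------------------------------------------------------------

def fit_opioid_logit(data: ModelData, random_effect: bool = True) -> ModelFit:
    """Risky (O -> OB/OS/OBS) versus non-risky (O -> zero) transitions.

    With ``random_effect`` a physician random intercept is integrated out
    by Gauss-Hermite quadrature (maximum likelihood); without it, a plain
    logistic fit.  Requires at least 10 events and 10 non-events.
    """
    df = data.frame
    mask = (df["from_mask"] == st.O) & df["to_mask"].isin([0, st.O | st.B, st.O | st.S, st.OBS_MASK])
    df = df[mask]
    y = (df["to_mask"] != 0).astype(int).to_numpy()
    if y.sum() < 10 or (1 - y).sum() < 10:
        raise ValueError(
            f"need >= 10 events and non-events, got {int(y.sum())} / {int((1 - y).sum())}"
        )
    predictors, dropped = _usable_predictors(df, data.predictors)
    X = sm.add_constant(df[predictors].to_numpy(dtype=float), prepend=True)
    names = ["intercept"] + list(predictors)

    if not random_effect:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        return _wald(
            res.params, res.bse, names, "log-odds", res.llf, X.shape[1],
            bool(res.mle_retvals.get("converged", True)), "Logit",
            extra={"statsmodels": res, "n_events": int(y.sum()),
                   "dropped_predictors": dropped},
        )

    groups = pd.factorize(df["responsible_physician_id"])[0]
    mres = _mixed.fit_logit_gh(X, y, groups)
    return _wald(
        mres.params[:-1], mres.bse[:-1], names, "log-odds", mres.loglik,
        mres.nparams, mres.converged, mres.method, vc=mres.vc,
        extra={"tau": float(mres.params[-1]), "n_events": int(y.sum()),
               "dropped_predictors": dropped},
    )


# ---------------------------------------------------------------------------
# Stage 3: Cox time-to-discontinuation of OBS
# ---------------------------------------------------------------------------

def fit_cox_obs(
    data: ModelData, frailty: bool = False, ties: str = "breslow"
) -> ModelFit:
    """Time to exit from state OBS (censored at end of follow-up).

    Model 1 (``frailty=False``): Cox partial likelihood (Breslow ties by
    default, Efron available).  Model 2: crossed log-normal patient and
    physician random intercepts via penalized partial likelihood; on
    non-convergence the fit is flagged and Model 1 results are attached.
    """
    df = data.frame
    dur = df["duration_days"].to_numpy(dtype=float)
    status = 1 - df["censored"].astype(int).to_numpy()
    if status.sum() < 10:
        raise ValueError(f"need >= 10 uncensored events, got {int(status.sum())}")
    predictors, dropped = _usable_predictors(df, data.predictors)
    X = df[predictors].to_numpy(dtype=float)
    names = list(predictors)

    model = PHReg(dur, X, status=status, ties=ties)
    res = model.fit(disp=0)
    base = _wald(
        res.params, res.bse, names, "log-hazard", model.loglike(res.params),
        X.shape[1], True, f"PHReg-{ties}",
        extra={"statsmodels": res, "n_events": int(status.sum()),
               "dropped_predictors": dropped},
    )
    if not frailty:
        return base

    pat = pd.factorize(df["patient_id"])[0]
    phys = pd.factorize(df["responsible_physician_id"])[0]
    mres = _mixed.fit_cox_frailty(X, dur, status, pat, phys)
    fit = _wald(
        mres.params, mres.bse, names, "log-hazard", mres.loglik, mres.nparams,
        mres.converged, mres.method, vc=mres.vc,
        extra={"n_events": int(status.sum()), "fallback_model1": base},
    )
    if not mres.converged:
        fit.extra["note"] = "frailty fit did not converge; see fallback_model1"
    return fit
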