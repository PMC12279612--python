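"""Seeded synthetic claims cohorts with known generating parameters.

The generator emulates the four claims-like tables the analysis consumes
(physician roster, patient roster, encounter log, prescription fill log)
with a known ground truth, so that every downstream stage -- network
construction, state timelines, and the three regression stages -- can be
tested for parameter recovery.

Generation is two-pass, because the models' predictors are functions of
the *observed* network: encounters are generated first, the shared-patient
network and its standardized positional measures are computed from them,
and prescribing is then simulated conditional on those realized measures.

The prescribing process mirrors the transition models.  At each encounter
the patient's next drug-count state is drawn from a 3-category
multinomial logit whose linear predictors apply the true coefficients to
the patient's covariates and the encountering physician's standardized
network measures, plus normal patient and physician random intercepts.
Additions become fill events prescribed by the encountering physician;
draws toward fewer drug groups are realized by stopping refills (the
dropped groups' exposure ends the day after the encounter, and the
encountering physician issues the final fill so that lapse attribution
points at the prescriber who made the decision).  Entry into the
all-three state (OBS) draws an exit time from an exponential
proportional-hazards model, after which all three groups lapse together.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from . import states as st
from .network import physician_metrics, standardize_measures

__all__ = [
    "SPECIALTIES", "SimConfig", "SimTruth", "ConfigError",
    "MissingMetricsError", "generate_rosters", "generate_encounters",
    "simulate_prescribing", "generate_cohort", "recovery_config",
]

SPECIALTIES = ("Primary Care", "Emergency Medicine", "Neurology", "Psychiatry", "Other")
#: cohort specialty mix: Primary Care / EM / Neurology / Psychiatry / Other
DEFAULT_SPECIALTY_PROPS = (0.4047, 0.1535, 0.0254, 0.0324, 0.3840)

#: predictor names understood in coefficient vectors
PREDICTORS = (
    "intercept", "age", "female", "race_black", "race_other",
    "closeness", "clustering", "volume",
    "spec_emergency", "spec_neurology", "spec_psychiatry", "spec_other",
    "closeness_x_volume",
)

# fixed substream labels so stages can be regenerated independently
_STREAM_ROSTERS, _STREAM_ENCOUNTERS, _STREAM_PRESCRIBING = 11, 23, 37


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class MissingMetricsError(KeyError):
    """An encountering physician has no network measures available."""


def _default_transition_coefficients() -> dict[str, dict[str, float]]:
    # Intercepts reproduce the observed from-zero split of roughly
    # 0.970 / 0.027 / 0.003 across 1-, 2-, and 3-drug prescribing.
    return {
        "cat2": {"intercept": -3.58},
        "cat3": {"intercept": -5.78},
    }


@dataclass
class SimConfig:
    """Generating parameters for a synthetic cohort.

    ``true_coefficients`` holds the fixed effects of the transition model
    on the log-odds scale, keyed ``"cat2"``/``"cat3"`` for the second and
    third outcome category relative to the first (lowest drug count)
    within each starting state; from state zero these are exactly the
    2-drug and 3-drug prescribing transitions.
    ``true_log_hazard_coefficients`` are log hazard ratios for the exit
    from state OBS, applied on top of ``baseline_exit_rate`` (events/day).
    """

    n_physicians: int = 200
    n_patients: int = 1000
    n_communities: int = 8
    study_days: int = 365
    encounter_rate: float = 8.0          # mean encounters per patient
    mixing: float = 0.2                  # prob. of encountering outside home community
    short_gap_fraction: float = 0.8      # fraction of encounter gaps <= 30 days
    gap_short_max: int = 30
    gap_long_max: int = 90
    specialty_props: tuple = DEFAULT_SPECIALTY_PROPS
    # O, B, S pick weights for added groups; default reproduces the observed
    # 0.94 share of from-zero single-drug starts going to O or B
    group_weights: tuple = (0.55, 0.39, 0.06)
    days_supply_min: int = 7
    days_supply_max: int = 30
    true_coefficients: dict = field(default_factory=_default_transition_coefficients)
    true_log_hazard_coefficients: dict = field(default_factory=dict)
    sigma_patient: float = 0.3           # SD of patient random intercept
    tau_physician: float = 0.3           # SD of physician random intercept
    baseline_exit_rate: float = 0.03     # OBS exit events/day at covariates 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_physicians", "n_patients", "n_communities", "study_days"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if self.study_days < 60:
            raise ConfigError("study_days must be >= 60 to exercise the 30-day rule")
        if self.encounter_rate <= 0 or self.baseline_exit_rate <= 0:
            raise ConfigError("rates must be positive")
        if self.sigma_patient < 0 or self.tau_physician < 0:
            raise ConfigError("random-effect SDs must be non-negative")
        if not 0 <= self.mixing <= 1 or not 0 <= self.short_gap_fraction <= 1:
            raise ConfigError("mixing and short_gap_fraction must be in [0, 1]")
        if abs(sum(self.specialty_props) - 1) > 1e-8 or min(self.specialty_props) < 0:
            raise ConfigError("specialty_props must be a probability vector")
        if not 1 <= self.days_supply_min <= self.days_supply_max:
            raise ConfigError("need 1 <= days_supply_min <= days_supply_max")
        for cat, coefs in self.true_coefficients.items():
            if cat not in ("cat2", "cat3"):
                raise ConfigError(f"unknown outcome category {cat!r}")
            for k in coefs:
                if k not in PREDICTORS:
                    raise ConfigError(f"unknown predictor {k!r} in true_coefficients")
        for k in self.true_log_hazard_coefficients:
            if k not in PREDICTORS:
                raise ConfigError(f"unknown predictor {k!r} in hazard coefficients")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class SimTruth:
    """Latent draws behind a simulated cohort (for recovery tests)."""

    config: SimConfig
    patient_random_effects: dict[str, float]
    physician_random_effects: dict[str, float]
    realized_network_measures: dict[str, dict[str, float]]
    patient_communities: dict[str, int] = field(default_factory=dict)
    physician_communities: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# Rosters and encounters
# ---------------------------------------------------------------------------

def generate_rosters(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Physician and patient rosters with Medicare-cohort-like descriptives.

    Specialty shares default to the study cohort mix; patient age is
    ``65 + Gamma(2, 4.2)`` rounded, calibrated to a median near 72; sex
    and race follow the cohort proportions.  Deterministic given the seed.
    """
    rng = config.rng(_STREAM_ROSTERS)
    n_p, n_k = config.n_physicians, config.n_patients

    width = max(4, len(str(n_p)))
    phys_ids = [f"D{i:0{width}d}" for i in range(n_p)]
    specialty = rng.choice(SPECIALTIES, size=n_p, p=np.asarray(config.specialty_props))
    # round-robin community assignment on a shuffled order: every community
    # is non-empty whenever n_physicians >= n_communities
    order = rng.permutation(n_p)
    phys_comm = np.empty(n_p, dtype=int)
    phys_comm[order] = np.arange(n_p) % config.n_communities
    physicians = pd.DataFrame(
        {"physician_id": phys_ids, "specialty": specialty, "community": phys_comm}
    )

    width_k = max(5, len(str(n_k)))
    pat_ids = [f"P{i:0{width_k}d}" for i in range(n_k)]
    age = 65 + np.round(rng.gamma(shape=2.0, scale=4.2, size=n_k)).astype(int)
    sex = np.where(rng.random(n_k) < 0.6562, "F", "M")
    race = rng.choice(["White", "Black", "Other"], size=n_k, p=[0.8625, 0.0864, 0.0511])
    pat_comm = rng.integers(0, config.n_communities, size=n_k)
    patients = pd.DataFrame(
        {"patient_id": pat_ids, "age": age, "sex": sex, "race": race, "community": pat_comm}
    )
    return physicians, patients


def generate_encounters(
    physicians: pd.DataFrame, patients: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Encounter log (patient, physician, day) with community structure.

    Each patient draws a Poisson number of encounters.  Physicians are
    sampled from the patient's home community with probability
    ``1 - mixing`` and uniformly otherwise, which induces community
    structure in the derived shared-patient network.  Consecutive gaps are
    short (<= ``gap_short_max`` days) with probability
    ``short_gap_fraction`` so the 30-day rule binds for most pairs.
    """
    if physicians.empty or patients.empty:
        raise ConfigError("rosters must be non-empty")
    rng = config.rng(_STREAM_ENCOUNTERS)
    by_comm = {
        c: grp["physician_id"].to_numpy()
        for c, grp in physicians.groupby("community")
    }
    all_phys = physicians["physician_id"].to_numpy()

    rows_pid, rows_doc, rows_date = [], [], []
    for pat in patients.itertuples(index=False):
        n = rng.poisson(config.encounter_rate)
        if n == 0:
            continue
        date = int(rng.integers(0, 31))
        dates = []
        for _ in range(n):
            if date >= config.study_days:
                break
            dates.append(date)
            if rng.random() < config.short_gap_fraction:
                gap = int(rng.integers(1, config.gap_short_max + 1))
            else:
                gap = int(rng.integers(config.gap_short_max + 1, config.gap_long_max + 1))
            date += gap
        home = by_comm.get(pat.community, all_phys)
        for d in dates:
            pool = all_phys if rng.random() < config.mixing else home
            rows_pid.append(pat.patient_id)
            rows_doc.append(str(rng.choice(pool)))
            rows_date.append(d)
    enc = pd.DataFrame(
        {"patient_id": rows_pid, "physician_id": rows_doc, "date": rows_date}
    )
    return enc.sort_values(["patient_id", "date", "physician_id"], kind="mergesort").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# Prescribing simulation
# ---------------------------------------------------------------------------

def _covariate_vector(patient, met_row, centers) -> dict[str, float]:
    # Network measures enter the generating predictors centered at the
    # cohort mean, so intercepts and the baseline exit rate describe an
    # average prescriber; logit/Cox slopes are invariant to centering.
    x = {
        "intercept": 1.0,
        "age": float(patient.age) - 75.0,
        "female": 1.0 if patient.sex == "F" else 0.0,
        "race_black": 1.0 if patient.race == "Black" else 0.0,
        "race_other": 1.0 if patient.race == "Other" else 0.0,
        "closeness": float(met_row["closeness"]) - centers["closeness"],
        "clustering": float(met_row["clustering"]) - centers["clustering"],
        "volume": float(met_row["volume"]) - centers["volume"],
        "spec_emergency": 1.0 if met_row["specialty"] == "Emergency Medicine" else 0.0,
        "spec_neurology": 1.0 if met_row["specialty"] == "Neurology" else 0.0,
        "spec_psychiatry": 1.0 if met_row["specialty"] == "Psychiatry" else 0.0,
        "spec_other": 1.0 if met_row["specialty"] == "Other" else 0.0,
    }
    x["closeness_x_volume"] = x["closeness"] * x["volume"]
    return x


def _lp(coefs: Mapping[str, float], x: Mapping[str, float]) -> float:
    return sum(v * x[k] for k, v in coefs.items())


class _PatientState:
    """Mutable per-patient exposure bookkeeping during simulation."""

    __slots__ = ("ends", "fill_idx", "fills")

    def __init__(self, fills: list) -> None:
        self.ends = {st.O: 0, st.B: 0, st.S: 0}  # exposure end per group
        self.fill_idx = {st.O: [], st.B: [], st.S: []}  # indices into self.fills
        self.fills = fills

    def active(self, day: int) -> list[int]:
        return [g for g in st.GROUPS if self.ends[g] > day]

    def add_fill(self, pid, doc, group, day, supply) -> None:
        self.fills.append(
            {
                "patient_id": pid,
                "prescriber_id": doc,
                "drug_group": st.GROUP_LETTERS[group],
                "fill_date": int(day),
                "days_supply": int(supply),
            }
        )
        self.fill_idx[group].append(len(self.fills) - 1)
        self.ends[group] = max(self.ends[group], day + supply)

    def set_group_end(self, group: int, end: int) -> None:
        """Force the group's exposure to end exactly at ``end``.

        Truncates any fill extending past ``end``; if current exposure
        stops earlier, the most recent fill is extended instead.
        """
        idxs = self.fill_idx[group]
        if self.ends[group] > end:
            for i in idxs:
                f = self.fills[i]
                if f["fill_date"] + f["days_supply"] > end:
                    f["days_supply"] = max(1, end - f["fill_date"])
            self.ends[group] = end
        elif self.ends[group] < end:
            last = max(idxs, key=lambda i: self.fills[i]["fill_date"])
            f = self.fills[last]
            f["days_supply"] = end - f["fill_date"]
            self.ends[group] = end


def simulate_prescribing(
    encounters: pd.DataFrame,
    physicians: pd.DataFrame,
    patients: pd.DataFrame,
    metrics_std: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate the fill log conditional on realized network measures.

    ``metrics_std`` must provide SD-standardized ``closeness``,
    ``clustering`` and ``volume`` plus ``specialty`` for every physician
    appearing in the encounter log; a missing physician raises
    :class:`MissingMetricsError` naming them.
    """
    rng = config.rng(_STREAM_PRESCRIBING)
    needed = pd.Index(encounters["physician_id"].unique())
    missing = needed.difference(metrics_std.index)
    if len(missing):
        raise MissingMetricsError(
            f"no network measures for encountering physician(s) {list(missing[:5])}"
        )

    theta = {
        p: float(rng.normal(0.0, config.sigma_patient))
        for p in patients["patient_id"]
    }
    gamma = {
        d: float(rng.normal(0.0, config.tau_physician))
        for d in physicians["physician_id"]
    }

    cat2 = config.true_coefficients.get("cat2", {})
    cat3 = config.true_coefficients.get("cat3", {})
    gw = np.asarray(config.group_weights, dtype=float)

    met_rows = {pid: metrics_std.loc[pid] for pid in needed}
    centers = {
        col: float(metrics_std.loc[needed, col].mean())
        for col in ("closeness", "clustering", "volume")
    }
    pat_rows = {p.patient_id: p for p in patients.itertuples(index=False)}
    xcache: dict[tuple[str, str], dict[str, float]] = {}

    fills: list[dict] = []
    supply_lo, supply_hi = config.days_supply_min, config.days_supply_max + 1

    for pid, enc in encounters.groupby("patient_id", sort=True):
        patient = pat_rows[pid]
        ps = _PatientState(fills)
        for row in enc.itertuples(index=False):
            d, doc = int(row.date), str(row.physician_id)
            active = ps.active(d)
            u = len(active)
            if u == 3:
                continue  # OBS dwell is governed by the exit-time model
            key = (pid, doc)
            x = xcache.get(key)
            if x is None:
                x = _covariate_vector(patient, met_rows[doc], centers)
                xcache[key] = x
            re = theta[pid] + gamma[doc]
            eta2 = _lp(cat2, x) + re
            eta3 = _lp(cat3, x) + re
            e = np.exp(np.array([0.0, eta2, eta3]) - max(0.0, eta2, eta3))
            p = e / e.sum()
            cats = sorted({0, 1, 2, 3} - {u})
            v = int(cats[rng.choice(3, p=p)])

            if v > u:
                missing_groups = [g for g in st.GROUPS if g not in active]
                w = gw[[st.GROUPS.index(g) for g in missing_groups]]
                pick = rng.choice(
                    len(missing_groups), size=v - u, replace=False, p=w / w.sum()
                )
                for j in sorted(pick):
                    g = missing_groups[j]
                    supply = int(rng.integers(supply_lo, supply_hi))
                    ps.add_fill(pid, doc, g, d, supply)
                if len(ps.active(d)) == 3:
                    # entry into OBS: exponential proportional-hazards exit
                    lam = config.baseline_exit_rate * math.exp(
                        _lp(config.true_log_hazard_coefficients, x) + re
                    )
                    dur = max(1, math.ceil(rng.exponential(1.0 / lam)))
                    for g in st.GROUPS:
                        ps.set_group_end(g, d + dur)
            elif v < u:
                if v > 0:
                    keep_idx = rng.choice(u, size=v, replace=False)
                    keep = {active[i] for i in keep_idx}
                else:
                    keep = set()
                for g in active:
                    if g not in keep:
                        ps.set_group_end(g, d + 1)
                if keep:
                    for g in sorted(keep):
                        supply = int(rng.integers(supply_lo, supply_hi))
                        ps.add_fill(pid, doc, g, d, supply)
                else:
                    # final 1-day fill marks the deciding prescriber before the lapse
                    g = active[0]  # O > B > S priority (GROUPS order)
                    ps.add_fill(pid, doc, g, d, 1)
                    ps.set_group_end(g, d + 1)

    fills_df = pd.DataFrame(
        fills, columns=["patient_id", "prescriber_id", "drug_group", "fill_date", "days_supply"]
    )
    truth = SimTruth(
        config=config,
        patient_random_effects=theta,
        physician_random_effects=gamma,
        realized_network_measures={
            pid: {
                "closeness": float(met_rows[pid]["closeness"]),
                "clustering": float(met_rows[pid]["clustering"]),
                "volume": float(met_rows[pid]["volume"]),
            }
            for pid in sorted(needed)
        },
        patient_communities={
            p.patient_id: int(p.community) for p in patients.itertuples(index=False)
        },
        physician_communities={
            p.physician_id: int(p.community) for p in physicians.itertuples(index=False)
        },
    )
    return fills_df, truth


# ---------------------------------------------------------------------------
# End-to-end cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig, window_days: int = 30) -> dict:
    """Rosters -> encounters -> network measures -> prescribing.

    The prescribing pass is restricted to encounters with physicians in
    the largest connected component, mirroring the analysis cohort (models
    use LCC prescribers; distance-based measures are undefined outside).
    Returns a dict with rosters, encounter log, metrics (raw and
    standardized), fill log, the graphs, and the :class:`SimTruth`.
    """
    physicians, patients = generate_rosters(config)
    encounters = generate_encounters(physicians, patients, config)
    if encounters.empty:
        raise ConfigError("no encounters generated; increase encounter_rate")
    metrics, g, lcc = physician_metrics(encounters, physicians, window_days)

    lcc_metrics = metrics[metrics["in_lcc"]].copy()
    lcc_metrics_std, sds = standardize_measures(
        lcc_metrics, ["closeness", "clustering", "volume"]
    )
    enc_lcc = encounters[encounters["physician_id"].isin(lcc_metrics_std.index)]
    n_dropped = len(encounters) - len(enc_lcc)
    fills, truth = simulate_prescribing(
        enc_lcc, physicians, patients, lcc_metrics_std, config
    )
    return {
        "physicians": physicians,
        "patients": patients,
        "encounters": encounters,
        "encounters_lcc": enc_lcc,
        "metrics": metrics,
        "metrics_std": lcc_metrics_std,
        "standardization_sds": sds,
        "network": g,
        "lcc": lcc,
        "fills": fills,
        "truth": truth,
        "n_encounters_outside_lcc": n_dropped,
    }


def recovery_config(seed: int, n_patients: int = 5000, n_physicians: int = 300) -> SimConfig:
    """Study conditions for the parameter-recovery simulation study.

    Fixed effects of realistic sign and size are placed on well-populated
    covariates; random-effect SDs are zero so the fixed-effect stages are
    evaluated against an exactly-specified marginal model.  Slopes are
    shared between the 2- and 3-drug categories, which makes the binary
    (risky-vs-zero) collapse of the transition model exactly logistic with
    the same slopes.  Follow-up is frequent and fills long (30-60 days) so
    prescribing decisions are made at encounters rather than by unmodeled
    lapses between visits.
    """
    slopes = {
        "age": -0.03,
        "female": 0.2,
        "closeness": math.log(0.8),
        "clustering": math.log(1.5),
        "volume": 0.15,
    }
    return SimConfig(
        n_physicians=n_physicians,
        n_patients=n_patients,
        n_communities=10,
        study_days=365,
        encounter_rate=22.0,
        mixing=0.2,
        short_gap_fraction=0.9,
        gap_short_max=28,
        gap_long_max=60,
        days_supply_min=30,
        days_supply_max=60,
        true_coefficients={
            "cat2": {"intercept": -1.4, **slopes},
            "cat3": {"intercept": -2.5, **slopes},
        },
        true_log_hazard_coefficients={
            "volume": 0.3,
            "clustering": 0.25,
            "female": 0.2,
        },
        sigma_patient=0.0,
        tau_physician=0.0,
        baseline_exit_rate=0.04,
        seed=seed,
    )
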