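"""End-to-end orchestration: simulate/load -> network -> states -> models.

A single :class:`PipelineConfig` drives the whole analysis and every
output is written as headered CSV (plus a JSON manifest), deterministically
for a fixed config and seed: rows are sorted, floats use a fixed format,
and the manifest carries no timestamps, so a rerun is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import states as st
from .models import (
    build_design_matrix,
    fit_cox_obs,
    fit_multinomial_transition,
    fit_opioid_logit,
)
from .network import physician_metrics, standardize_measures
from .simulate import SimConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "render_reports", "load_tables"]

log = logging.getLogger("rxnet")

_FLOAT_FMT = "%.12g"

TABLE_COLUMNS = {
    "encounters": ["patient_id", "physician_id", "date"],
    "fills": ["patient_id", "prescriber_id", "drug_group", "fill_date", "days_supply"],
    "physicians": ["physician_id", "specialty"],
    "patients": ["patient_id", "age", "sex", "race"],
}


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of ``sim`` (a :class:`~rxnet.simulate.SimConfig`) or
    ``inputs`` (paths to the four claims tables) must be provided.
    """

    sim: SimConfig | None = None
    inputs: dict | None = None
    window_days: int = 30
    study_days: int = 365
    exposure_mode: str = "union"
    random_effects: bool = False
    interaction: bool = False
    starting_states: tuple = (0,)
    out_dir: str = "rxnet_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ValueError("provide exactly one of `sim` or `inputs`")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        if self.exposure_mode not in ("union", "extension"):
            raise ValueError("exposure_mode must be 'union' or 'extension'")
        if self.sim is not None:
            self.study_days = self.sim.study_days


def load_tables(inputs: dict) -> dict:
    """Read the four claims tables from CSV paths."""
    out = {}
    for name, cols in TABLE_COLUMNS.items():
        df = pd.read_csv(inputs[name], dtype={c: str for c in cols if c.endswith("_id")})
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"{name} table missing columns {sorted(missing)}")
        out[name] = df
    return out


def _standardized_model_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Full-roster metrics with SD-standardized modeling columns.

    SDs are computed over LCC physicians (the modeling population);
    physicians outside the LCC keep NaN measures and are excluded from
    model rows via the ``in_lcc`` flag.
    """
    lcc = metrics[metrics["in_lcc"]]
    _, sds = standardize_measures(lcc.copy(), ["closeness", "clustering", "volume"])
    out = metrics.copy()
    for col, sd in sds.items():
        out[col] = out[col] / sd
    out.loc[~out["in_lcc"], ["closeness", "clustering", "volume"]] = np.nan
    out.attrs["standardization_sds"] = sds
    return out


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> int:
    df.to_csv(path, index=index, float_format=_FLOAT_FMT, lineterminator="\n")
    return len(df)


def _fit_results_record(name: str, fit) -> tuple[pd.DataFrame, dict]:
    frame = fit.summary_frame().reset_index(names="predictor")
    frame.insert(0, "model", name)
    sidecar = {
        "model": name,
        "method": fit.method,
        "loglik": fit.loglik,
        "aic": fit.aic,
        "converged": fit.converged,
        "variance_components": fit.vc,
        "scale": fit.scale,
    }
    return frame, sidecar


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write outputs; returns the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "rxnet_version": __version__,
        "seed": config.seed,
        "files": {},
        "exclusions": {},
        "skipped_models": [],
    }

    # ---- stage: data ------------------------------------------------------
    if config.sim is not None:
        cohort = generate_cohort(config.sim, window_days=config.window_days)
        physicians, patients = cohort["physicians"], cohort["patients"]
        encounters, fills = cohort["encounters"], cohort["fills"]
        metrics = cohort["metrics"]
        manifest["exclusions"]["encounters_outside_lcc"] = cohort["n_encounters_outside_lcc"]
        g, lcc = cohort["network"], cohort["lcc"]
        for name in ("encounters", "fills", "physicians", "patients"):
            df = cohort[name][TABLE_COLUMNS[name]]
            manifest["files"][f"{name}.csv"] = _write_csv(df, out / f"{name}.csv")
        (out / "sim_truth.json").write_text(cohort["truth"].to_json())
        manifest["files"]["sim_truth.json"] = 1
    else:
        tables = load_tables(config.inputs)
        physicians, patients = tables["physicians"], tables["patients"]
        encounters, fills = tables["encounters"], tables["fills"]
        metrics, g, lcc = physician_metrics(encounters, physicians, config.window_days)
    model_metrics = _standardized_model_metrics(metrics)

    # ---- stage: network ---------------------------------------------------
    edges = pd.DataFrame(
        [(min(a, b), max(a, b), d["weight"]) for a, b, d in g.edges(data=True)],
        columns=["physician_a", "physician_b", "weight"],
    ).sort_values(["physician_a", "physician_b"]).reset_index(drop=True)
    manifest["files"]["edges.csv"] = _write_csv(edges, out / "edges.csv")
    metrics_out = metrics.reset_index().sort_values("physician_id")
    manifest["files"]["metrics.csv"] = _write_csv(metrics_out, out / "metrics.csv")

    # ---- stage: states ----------------------------------------------------
    study_end = config.study_days
    result = st.analyze_cohort(fills, study_end, mode=config.exposure_mode)
    transitions = st.transitions_to_frame(result["transitions"])
    matrix = result["matrix"]
    durations = pd.DataFrame(
        result["durations"],
        columns=["patient_id", "entry_date", "duration_days", "censored",
                 "responsible_physician_id"],
    )
    n_zero_fill = patients["patient_id"].nunique() - fills["patient_id"].nunique()
    manifest["exclusions"]["patients_without_fills"] = int(n_zero_fill)
    manifest["exclusions"]["ambiguous_attributions"] = int(result["n_ambiguous"])
    manifest["files"]["transitions.csv"] = _write_csv(transitions, out / "transitions.csv")
    manifest["files"]["transition_matrix.csv"] = _write_csv(
        matrix.to_frame(), out / "transition_matrix.csv"
    )
    manifest["files"]["durations.csv"] = _write_csv(durations, out / "durations.csv")

    # ---- stage: models ----------------------------------------------------
    frames, sidecars = [], []
    n_model_rows = 0
    if len(transitions):
        data = build_design_matrix(
            transitions, model_metrics, patients, interaction=config.interaction,
        )
        manifest["exclusions"]["transitions_outside_lcc"] = data.n_excluded
        n_model_rows = len(data.frame)
        for start in config.starting_states:
            name = f"multinomial_from_{start}"
            try:
                fit = fit_multinomial_transition(
                    data, start_count=start, random_effects=config.random_effects
                )
                f, s = _fit_results_record(name, fit)
                frames.append(f)
                sidecars.append(s)
            except ValueError as err:
                manifest["skipped_models"].append({"model": name, "reason": str(err)})
        try:
            fit = fit_opioid_logit(data, random_effect=config.random_effects)
            f, s = _fit_results_record("opioid_logit", fit)
            frames.append(f)
            sidecars.append(s)
        except ValueError as err:
            manifest["skipped_models"].append({"model": "opioid_logit", "reason": str(err)})
        if len(durations):
            dur_data = build_design_matrix(
                durations.assign(drug_count_from=3, drug_count_to=0,
                                 from_mask=st.OBS_MASK, to_mask=0),
                model_metrics, patients, interaction=config.interaction,
            )
            for frailty, name in ((False, "cox_obs_model1"), (True, "cox_obs_model2")):
                if frailty and not config.random_effects:
                    continue
                try:
                    fit = fit_cox_obs(dur_data, frailty=frailty)
                    f, s = _fit_results_record(name, fit)
                    frames.append(f)
                    sidecars.append(s)
                except ValueError as err:
                    manifest["skipped_models"].append({"model": name, "reason": str(err)})
    if frames:
        results = pd.concat(frames, ignore_index=True)
    else:
        results = pd.DataFrame(columns=["model", "predictor"])
    manifest["files"]["model_results.csv"] = _write_csv(results, out / "model_results.csv")
    (out / "model_results.json").write_text(
        json.dumps(sidecars, sort_keys=True, indent=1, default=float)
    )
    manifest["files"]["model_results.json"] = len(sidecars)

    # ---- stage: report ----------------------------------------------------
    report = render_reports(matrix, result["transitions"], metrics)
    (out / "report.txt").write_text(report)
    manifest["files"]["report.txt"] = report.count("\n")

    manifest["row_counts"] = {
        "encounters": int(len(encounters)),
        "fills": int(len(fills)),
        "transitions": int(len(transitions)),
        "model_rows": int(n_model_rows),
        "obs_spells": int(len(durations)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _median_iqr(values: pd.Series) -> str:
    """Median (IQR) with linear-interpolation quantiles."""
    v = values.dropna().to_numpy(dtype=float)
    if len(v) == 0:
        return "n/a"
    q1, q2, q3 = np.percentile(v, [25, 50, 75])
    return f"{q2:.4g} ({q1:.4g}, {q3:.4g})"


def render_reports(
    matrix: st.TransitionMatrix,
    transitions: list,
    metrics: pd.DataFrame,
) -> str:
    """Human-readable report: 8x8 matrix, collapsed diagram, descriptives.

    Betweenness and eigenvector centrality are rescaled by 1e5 in the
    descriptive table for readability (raw values are used in models).
    """
    lines = []
    lines.append("8-state transition probability matrix (rows: from, cols: to)")
    header = "from/to " + " ".join(f"{s:>7}" for s in st.STATE_NAMES)
    lines.append(header)
    undefined = []
    for i, name in enumerate(st.STATE_NAMES):
        if matrix.defined_rows[i]:
            cells = " ".join(f"{matrix.probabilities[i, j]:7.3f}" for j in range(8))
            lines.append(f"{name:>7} {cells}")
        else:
            undefined.append(name)
    if undefined:
        lines.append(f"rows with no observed transitions: {', '.join(undefined)}")

    lines.append("")
    lines.append("Collapsed drug-count transitions (out-edge probabilities)")
    counts = np.zeros((4, 4))
    for r in transitions:
        counts[r.drug_count_from, r.drug_count_to] += 1
    for u in range(4):
        total = counts[u].sum()
        if total == 0:
            lines.append(f"  from {u}-drug: no transitions observed")
            continue
        probs = ", ".join(
            f"->{v}: {counts[u, v] / total:.3f}" for v in range(4) if v != u and counts[u, v] > 0
        )
        lines.append(f"  from {u}-drug (n={int(total)}): {probs}")

    lines.append("")
    lines.append("Physician network measures, LCC prescribers: median (IQR)")
    lcc = metrics[metrics["in_lcc"]] if "in_lcc" in metrics.columns else metrics
    display = {
        "strength": 1.0, "degree": 1.0, "closeness": 1.0,
        "betweenness": 1e5, "eigenvector": 1e5, "clustering": 1.0,
        "volume": 1.0,
    }
    for measure, scale in display.items():
        if measure not in lcc.columns:
            continue
        label = measure + (" (x1e5)" if scale != 1.0 else "")
        lines.append(f"  {label:>20}: {_median_iqr(lcc[measure] * scale)}")
    lines.append("")
    lines.append("quantile convention: linear interpolation")
    return "\n".join(lines) + "\n"
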