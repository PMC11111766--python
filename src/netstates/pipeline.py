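"""End-to-end driver: conditioning -> sFNC -> dFNC -> metrics -> statistics.

``run_pipeline`` executes every stage on a cohort directory (or an
in-memory cohort), writes the per-stage tables, and returns a JSON-ready
report carrying the config echo and hash, per-stage record counts, the
demographics comparison, connectivity contrasts at both granularities,
per-state dynamic contrasts, the temporal-metric table, and the clinical
correlation analyses.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import dfnc, metrics as met, prep, sfnc, stats
from .io import RunConfig, read_cohort, write_cohort
from .types import ComponentTimecourses

__all__ = ["run_pipeline", "analyze_cohort"]

log = logging.getLogger(__name__)


def _demographics_table(clinical: pd.DataFrame) -> dict:
    """Demographics/clinical comparison (t for continuous, chi2 for sex)."""
    pat = clinical[clinical["group"] == "PACG"]
    ctl = clinical[clinical["group"] == "HC"]
    out: dict = {"n_patients": len(pat), "n_controls": len(ctl)}
    for var in ("age", "education", "IOP", "RNFLT", "VA",
                "ACD_ratio", "VCD_ratio"):
        if var not in clinical.columns:
            continue
        t, df, p = stats.two_sample_t(pat[var].dropna(), ctl[var].dropna())
        out[var] = {"patient_mean": float(pat[var].mean()),
                    "patient_sd": float(pat[var].std(ddof=1)),
                    "control_mean": float(ctl[var].mean()),
                    "control_sd": float(ctl[var].std(ddof=1)),
                    "t": t, "df": df, "p": p}
    counts = np.array([
        [int((pat["sex"] == "M").sum()), int((pat["sex"] == "F").sum())],
        [int((ctl["sex"] == "M").sum()), int((ctl["sex"] == "F").sum())],
    ])
    chi2, df, p = stats.chi_square_2x2(counts)
    out["sex"] = {"table": counts.tolist(), "chi2": chi2, "df": df, "p": p}
    if "duration" in clinical.columns and pat["duration"].notna().any():
        q1, q2, q3 = pat["duration"].quantile([0.25, 0.5, 0.75])
        out["duration"] = {"median": float(q2),
                           "q1": float(q1), "q3": float(q3)}
    return out


def _correlation_analyses(clinical: pd.DataFrame, metric_frame: pd.DataFrame,
                          net_contrast: pd.DataFrame,
                          net_values: pd.DataFrame, k: int) -> list[dict]:
    """Clinical correlations within the patient group.

    Partial Pearson (controlling age and sex) between each state's
    occupancy and IOP/RNFLT/VA, plus Spearman between each significant
    network-pair sFNC unit and disease duration; both raw and adjusted
    duration correlations are reported.
    """
    pat = clinical[clinical["group"] == "PACG"].set_index("subject_id")
    mf = metric_frame.set_index("subject_id").loc[pat.index]
    cov = np.column_stack([pat["age"].to_numpy(float),
                           (pat["sex"] == "F").to_numpy(float)])
    results = []
    for j in range(1, k + 1):
        for var in ("IOP", "RNFLT", "VA"):
            if var not in pat.columns:
                continue
            res = stats.partial_pearson(
                mf[f"fraction_state{j}"].to_numpy(), pat[var].to_numpy(float),
                cov, attribute_label=f"fraction_state{j}", clinical_label=var,
                covariate_labels=["age", "sex"])
            results.append(res.__dict__ | {"covariates": ["age", "sex"]})
    if "duration" in pat.columns and pat["duration"].notna().all():
        sig_units = net_contrast.loc[net_contrast["significant"], "unit"]
        for unit in sig_units:
            vals = net_values.set_index("subject_id").loc[pat.index, unit]
            res = stats.spearman(vals.to_numpy(), pat["duration"].to_numpy(float),
                                 attribute_label=unit, clinical_label="duration")
            results.append(res.__dict__)
            adj = stats.partial_pearson(
                vals.to_numpy(), pat["duration"].to_numpy(float), cov,
                attribute_label=unit, clinical_label="duration",
                covariate_labels=["age", "sex"])
            results.append(adj.__dict__ | {"covariates": ["age", "sex"]})
    return results


def analyze_cohort(tcs: list[ComponentTimecourses], clinical: pd.DataFrame,
                   config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run every analysis stage on an in-memory cohort; returns the report."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "sfnc_matrices").mkdir(parents=True, exist_ok=True)
        (out / "assignments").mkdir(parents=True, exist_ok=True)

    # conditioning
    pcfg = prep.PrepConfig(
        detrend_order=config.detrend_order, do_detrend=config.do_detrend,
        do_despike=config.do_despike, despike_z=config.despike_z,
        do_lowpass=config.do_lowpass, cutoff_hz=config.cutoff_hz)
    conditioned = [prep.preprocess(tc, pcfg) for tc in tcs]

    # static FNC + contrast
    fnc = {tc.subject_id: sfnc.compute_sfnc(tc) for tc in conditioned}
    comp_res, net_res = sfnc.sfnc_group_contrast(
        fnc, clinical, covariates=list(config.covariates),
        alpha=config.fdr_alpha)
    comp_frame = sfnc.contrast_frame(comp_res)
    net_frame = sfnc.contrast_frame(net_res)

    # per-subject network-pair sFNC values (for clinical correlations)
    first = next(iter(fnc.values()))
    Y = np.vstack([fnc[sid].upper() for sid in fnc])
    net_Y, net_labels = sfnc.network_pair_frame(
        Y, first.component_labels, first.networks)
    net_values = pd.DataFrame(net_Y, columns=net_labels)
    net_values.insert(0, "subject_id", list(fnc))

    # dynamic FNC
    taper = dfnc.build_taper(config.window_width, config.window_sigma,
                             crop_to_width=config.crop_to_width)
    windowed = {tc.subject_id: dfnc.windowed_fnc(
        tc, taper, step=config.window_step, fisher=config.fisher_windows)
        for tc in conditioned}
    model = dfnc.kmeans_states(windowed, k=config.k_states,
                               reps=config.kmeans_reps,
                               max_iter=config.kmeans_max_iter,
                               seed=config.seed)
    state_res = dfnc.state_group_contrast(model, windowed, clinical,
                                          alpha=config.fdr_alpha)

    # temporal metrics
    tmetrics = [met.compute_metrics(sid, model.assignments[sid], model.k,
                                    config.dwell_absent_policy)
                for sid in windowed]
    metric_frame = met.metrics_frame(tmetrics)
    metric_contrast = met.metrics_group_contrast(tmetrics, clinical,
                                                 alpha=config.fdr_alpha)

    correlations = _correlation_analyses(clinical, metric_frame, net_frame,
                                         net_values, model.k)

    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_subjects": len(tcs),
        "n_windows_per_subject": int(next(iter(windowed.values())).n_windows),
        "demographics": _demographics_table(clinical),
        "sfnc_contrast_networks": net_frame.to_dict(orient="records"),
        "sfnc_significant_components": comp_frame.loc[
            comp_frame["significant"], "unit"].tolist(),
        "state_occupancy_overall": {
            f"state{j}": float(np.mean(np.concatenate(
                [model.assignments[s] == j for s in model.assignments])))
            for j in range(1, model.k + 1)},
        "kmeans_best_cost": model.best_cost,
        "state_contrasts": {
            str(j): [r.__dict__ for r in res] for j, res in state_res.items()},
        "temporal_metrics_table": metric_contrast.to_dict(orient="records"),
        "correlations": correlations,
    }

    if out is not None:
        for sid, m in fnc.items():
            pd.DataFrame(m.values, index=m.component_labels,
                         columns=m.component_labels).to_csv(
                out / "sfnc_matrices" / f"{sid}.tsv", sep="\t")
        comp_frame.to_csv(out / "sfnc_contrast_components.csv", index=False)
        net_frame.to_csv(out / "sfnc_contrast_networks.csv", index=False)
        pd.DataFrame(model.centroids, columns=model.pair_labels).to_csv(
            out / "centroids.tsv", sep="\t", index=False)
        for sid, a in model.assignments.items():
            pd.DataFrame({"state": a}).to_csv(
                out / "assignments" / f"{sid}.tsv", sep="\t", index=False)
        metric_frame.to_csv(out / "metrics.csv", index=False)
        metric_contrast.to_csv(out / "temporal_metrics_contrast.csv",
                               index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
    return report


def run_pipeline(config: RunConfig, in_dir: str | Path,
                 out_dir: str | Path) -> dict:
    """Read a cohort directory, run every stage, write outputs + report."""
    tcs, clinical = read_cohort(in_dir)
    log.info("pipeline: %d subjects from %s", len(tcs), in_dir)
    return analyze_cohort(tcs, clinical, config, out_dir)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
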