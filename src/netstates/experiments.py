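"""Cohort-level validation experiments.

Self-contained experiments that exercise the full pipeline against known
ground truth: recovery of planted connectivity states, calibration of the
group statistics under a null cohort, and power recovery for the planted
occupancy contrast.  The printed summary statistics of the emulated
PACG/HC cohort (demographics and temporal-metric tables) are bundled here
as inputs for recomputation checks.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import dfnc, sfnc, stats, synth
from .metrics import metrics_group_contrast

__all__ = [
    "DEMOGRAPHICS_SUMMARY", "TEMPORAL_METRICS_SUMMARY",
    "recompute_demographics_pvalues", "recompute_t_to_p_bridge",
    "planted_state_recovery", "null_calibration", "occupancy_power_recovery",
]

#: Printed demographics of the emulated cohort: (mean, sd) per group, or
#: a 2x2 sex count table.  These are recomputation inputs, not outputs.
DEMOGRAPHICS_SUMMARY = {
    "age": {"PACG": (53.12, 11.75, 34), "HC": (52.85, 10.61, 33)},
    "education": {"PACG": (9.44, 2.76, 34), "HC": (9.91, 2.70, 33)},
    "sex_counts": [[16, 18], [16, 17]],  # rows: PACG, HC; cols: M, F
}

#: Printed per-state temporal-metric t statistics of the emulated cohort
#: (group df = 34 + 33 - 2 = 65), with their reported two-sided p-values.
TEMPORAL_METRICS_SUMMARY = {
    "df": 65,
    "t_and_p": [
        ("fraction_state1", -0.245, 0.807),
        ("dwell_state1", 0.317, 0.752),
        ("fraction_state2", 0.369, 0.713),
        ("dwell_state2", -0.284, 0.778),
        ("fraction_state3", -2.21, 0.031),
        ("dwell_state3", -1.119, 0.267),
        ("fraction_state4", 1.964, 0.054),
        ("dwell_state4", 1.876, 0.065),
        ("n_transitions", -0.718, 0.475),
    ],
    "fraction_state3_groups": {"PACG": (0.10, 0.20, 34), "HC": (0.22, 0.25, 33)},
}


def recompute_demographics_pvalues() -> dict[str, float]:
    """Group-difference p-values recomputed from the printed summaries."""
    out = {}
    for var in ("age", "education"):
        (m1, s1, n1) = DEMOGRAPHICS_SUMMARY[var]["PACG"]
        (m2, s2, n2) = DEMOGRAPHICS_SUMMARY[var]["HC"]
        _, _, p = stats.t_from_summary(m1, s1, n1, m2, s2, n2)
        out[var] = p
    _, _, p = stats.chi_square_2x2(DEMOGRAPHICS_SUMMARY["sex_counts"])
    out["sex"] = p
    return out


def recompute_t_to_p_bridge() -> list[tuple[str, float, float, float]]:
    """(metric, printed t, recomputed p, reported p) per temporal metric."""
    df = TEMPORAL_METRICS_SUMMARY["df"]
    return [(name, t, stats.p_from_t(t, df), p_pub)
            for name, t, p_pub in TEMPORAL_METRICS_SUMMARY["t_and_p"]]


def planted_state_recovery(seed: int = 1, kmeans_reps: int = 150,
                           max_iter: int = 500, elbow_reps: int = 5) -> dict:
    """Cluster a well-separated synthetic cohort and score recovery.

    Simulates the recovery-regime cohort (67 subjects, T=230, C=16, four
    archetypal states with slow switching), runs tapered windowing plus
    cityblock k-means at the reference settings, and reports the adjusted
    Rand index against the taper-weighted true window states together with
    the elbow-selected k over 2..8.
    """
    spec = synth.recovery_spec(seed=seed)
    tcs, _, gt = synth.simulate_cohort(spec)
    taper = dfnc.build_taper()
    windowed = {tc.subject_id: dfnc.windowed_fnc(tc, taper) for tc in tcs}
    model = dfnc.kmeans_states(windowed, k=spec.k_states, reps=kmeans_reps,
                               max_iter=max_iter, seed=seed + 100)
    true = np.concatenate([
        synth.window_states(gt.state_sequences[tc.subject_id], taper.length,
                            weights=taper.weights) for tc in tcs])
    pred = np.concatenate([model.assignments[tc.subject_id] for tc in tcs])
    k_sel, curve = dfnc.elbow_select_k(windowed, range(2, 9),
                                       reps=elbow_reps, max_iter=max_iter,
                                       seed=seed + 7)
    return {"ari": float(adjusted_rand_score(true, pred)),
            "k_selected": int(k_sel),
            "elbow_curve": curve,
            "n_windows": int(pred.size)}


def null_calibration(seed: int = 0, n_replicates: int = 500,
                     n_patients: int = 34, n_controls: int = 33,
                     n_components: int = 6, n_timepoints: int = 120) -> dict:
    """False-positive calibration under identical groups.

    Both groups share one Markov chain and one state set, so every group
    test is null.  Per replicate, the fraction of BH-FDR-significant
    static-connectivity units (covariate-adjusted contrast) and
    temporal-metric tests (on the true state sequences) is recorded.
    The generator plants no trends or spikes, so connectivity is computed
    on the raw simulated series.
    """
    frac_sfnc, frac_metrics = [], []
    for rep in range(n_replicates):
        spec = synth.CohortSpec(
            n_patients=n_patients, n_controls=n_controls,
            n_components=n_components, n_timepoints=n_timepoints,
            min_window_length=min(n_timepoints, 48),
            clinical_coupling=[], seed=seed * n_replicates + rep)
        spec.transition_matrix_patient = spec.transition_matrix_control
        tcs, clinical, gt = synth.simulate_cohort(spec)
        fnc = {tc.subject_id: sfnc.compute_sfnc(tc) for tc in tcs}
        comp, _ = sfnc.sfnc_group_contrast(fnc, clinical)
        frac_sfnc.append(np.mean([r.significant for r in comp]))
        table = metrics_group_contrast(list(gt.true_metrics.values()), clinical)
        frac_metrics.append(table["significant"].mean())
    frac_sfnc = np.asarray(frac_sfnc)
    frac_metrics = np.asarray(frac_metrics)
    return {
        "sfnc_significant_fraction": float(frac_sfnc.mean()),
        "sfnc_mc_se": float(frac_sfnc.std(ddof=1) / np.sqrt(n_replicates)),
        "metrics_significant_fraction": float(frac_metrics.mean()),
        "metrics_mc_se": float(frac_metrics.std(ddof=1) / np.sqrt(n_replicates)),
        "n_replicates": n_replicates,
    }


def occupancy_power_recovery(seed: int = 0, n_replicates: int = 500) -> dict:
    """Rejection rate for the planted state-3 occupancy contrast.

    Draws group samples from the printed summary distributions (patients
    0.10 +- 0.20, n=34; controls 0.22 +- 0.25, n=33), applies the pooled
    two-sample t-test at alpha = 0.05, and compares the Monte-Carlo
    rejection rate with the exact noncentral-t power at the pooled-SD
    effect size.
    """
    (m1, s1, n1) = TEMPORAL_METRICS_SUMMARY["fraction_state3_groups"]["PACG"]
    (m2, s2, n2) = TEMPORAL_METRICS_SUMMARY["fraction_state3_groups"]["HC"]
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        x = rng.normal(m1, s1, n1)
        y = rng.normal(m2, s2, n2)
        _, _, p = stats.two_sample_t(x, y)
        rejections += p < 0.05
    pooled_sd = np.sqrt(((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2)
                        / (n1 + n2 - 2))
    d = abs(m1 - m2) / pooled_sd
    predicted = stats.power_two_sample_t(d, n1, n2)
    return {"rejection_rate": rejections / n_replicates,
            "effect_size_d": float(d),
            "predicted_power": float(predicted),
            "n_replicates": n_replicates}
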