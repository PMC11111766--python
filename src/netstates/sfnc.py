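"""Static functional network connectivity (sFNC).

Whole-scan pairwise Pearson correlations between component time courses,
Fisher z-transformed, and a covariate-adjusted group contrast per
connectivity unit with Benjamini-Hochberg FDR.

The group contrast fits, for each connectivity unit, an ordinary least
squares model ``z ~ intercept + group + covariates`` (default covariates:
age, sex, education) and tests the group coefficient; this reduces exactly
to the pooled two-sample t-test when no covariates are supplied.  Results
come at two granularities — raw component pairs and network pairs (the
average of member component-pair z values per subject) — each FDR-corrected
within its own family.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .stats import GroupTestResult, bh_fdr, p_from_t
from .types import ComponentTimecourses, FNCMatrix

__all__ = ["fisher_z", "compute_sfnc", "network_pair_frame",
           "sfnc_group_contrast", "contrast_frame"]

log = logging.getLogger(__name__)

_R_CLIP = 1.0 - 1e-7


def fisher_z(r):
    """Fisher z-transform ``arctanh(r)``; |r| = 1 is clipped to 1 - 1e-7."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlation magnitude exceeds 1")
    if np.any(np.abs(r) >= _R_CLIP):
        warnings.warn("correlation at +-1 clipped before Fisher z", stacklevel=2)
        r = np.clip(r, -_R_CLIP, _R_CLIP)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def compute_sfnc(tc: ComponentTimecourses) -> FNCMatrix:
    """Pairwise Fisher-z correlations over the full scan, zero diagonal.

    Zero-variance components yield 0 entries (with a warning naming the
    component) rather than NaNs.
    """
    if tc.n_timepoints < 3:
        raise ValueError("need at least 3 time points for a correlation")
    data = tc.data
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    for c in dead:
        warnings.warn(
            f"component {tc.component_labels[c]} has zero variance; "
            "its connectivity set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data, rowvar=False)
    r[~np.isfinite(r)] = 0.0
    np.fill_diagonal(r, 0.0)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    return FNCMatrix(subject_id=tc.subject_id, values=z,
                     component_labels=list(tc.component_labels),
                     networks=tc.networks())


def _pair_index(C: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(C, k=1)


def network_pair_frame(vectors: np.ndarray, component_labels: list[str],
                       networks: list[str]) -> tuple[np.ndarray, list[str]]:
    """Average component-pair z values into network-pair units.

    ``vectors`` is n_subjects x P (upper-triangle order).  Within-network
    units are included (the average over a network's internal pairs) for
    networks with more than one component.
    """
    C = len(component_labels)
    iu, ju = _pair_index(C)
    pair_nets = [tuple(sorted((networks[i], networks[j])))
                 for i, j in zip(iu, ju)]
    order = sorted(set(pair_nets))
    cols, labels = [], []
    for a, b in order:
        mask = np.array([pn == (a, b) for pn in pair_nets])
        cols.append(vectors[:, mask].mean(axis=1))
        labels.append(f"{a}--{b}")
    return np.column_stack(cols), labels


def _ols_group_contrast(Y: np.ndarray, group: np.ndarray,
                        covariates: np.ndarray | None,
                        labels: list[str], alpha: float) -> list[GroupTestResult]:
    """OLS of each column of Y on [1, group, covariates]; t on group."""
    n = Y.shape[0]
    parts = [np.ones(n), group.astype(float)]
    if covariates is not None and covariates.size:
        parts.append(covariates)
    X = np.column_stack(parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns for the caller
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
                bad.append(j)
        raise ValueError(f"rank-deficient design; collinear columns {bad}")
    df = n - X.shape[1]
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y                       # p x P
    resid = Y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(XtX_inv[1, 1] * sigma2)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = np.where(se > 0, beta[1] / se, 0.0)
    pvals = np.array([p_from_t(t, df) for t in tstat])
    p_adj = bh_fdr(pvals)
    return [
        GroupTestResult(unit_label=lab, estimate=float(beta[1, j]),
                        t_stat=float(tstat[j]), df=df, p=float(pvals[j]),
                        p_fdr=float(p_adj[j]), significant=bool(p_adj[j] < alpha))
        for j, lab in enumerate(labels)
    ]


def sfnc_group_contrast(fnc_by_subject: dict[str, FNCMatrix],
                        clinical: pd.DataFrame,
                        covariates: list[str] = ("age", "sex", "education"),
                        alpha: float = 0.05,
                        ) -> tuple[list[GroupTestResult], list[GroupTestResult]]:
    """Covariate-adjusted group contrast of static FNC.

    Returns ``(component_level, network_level)`` result lists, each
    BH-FDR-corrected within its own granularity.  Sex is encoded 0/1
    (M=0, F=1); group is 1 for patients (PACG), 0 for controls.
    """
    clin = clinical.set_index("subject_id")
    sids = list(fnc_by_subject)
    missing = [s for s in sids if s not in clin.index]
    if missing:
        raise ValueError(f"subjects without clinical rows: {missing}")
    first = fnc_by_subject[sids[0]]
    comp_labels = first.component_labels
    Y = np.vstack([fnc_by_subject[s].upper() for s in sids])
    group = (clin.loc[sids, "group"] == "PACG").to_numpy(int)
    cov_cols = []
    for c in covariates:
        v = clin.loc[sids, c]
        if c == "sex":
            v = (v == "F").astype(float)
        cov_cols.append(v.to_numpy(float))
    cov = np.column_stack(cov_cols) if cov_cols else None

    comp_results = _ols_group_contrast(Y, group, cov, first.pair_labels, alpha)

    # network-level: average member-pair z per subject, separate FDR family
    if first.networks is None:
        raise ValueError(
            "network-level contrast requires FNCMatrix.networks "
            "(set by compute_sfnc from the component->network map)")
    net_Y, net_labels = network_pair_frame(Y, comp_labels, first.networks)
    net_results = _ols_group_contrast(net_Y, group, cov, net_labels, alpha)
    return comp_results, net_results


def contrast_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    """Tabular view: unit, estimate, t, df, p, p_fdr, significant."""
    return pd.DataFrame([
        {"unit": r.unit_label, "estimate": r.estimate, "t": r.t_stat,
         "df": r.df, "p": r.p, "p_fdr": r.p_fdr, "significant": r.significant}
        for r in results
    ])
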