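"""Dynamic functional network connectivity (dFNC).

Connectivity is re-estimated inside a tapered sliding window — a 30-TR
rectangle convolved with a Gaussian of sigma = 3 TRs, stepped 1 TR at a
time — giving each subject a sequence of Fisher-z connectivity vectors.
Pooling every subject's windows, k-means under the cityblock (L1) distance
with componentwise-median centroid updates partitions the windows into a
small set of recurring connectivity states; the number of states is chosen
by the elbow criterion on the within/between cluster dispersion ratio.

Design notes
------------
* The convolution lengthens the taper's support beyond the nominal
  rectangle width; windows slide over the full extended length L
  (``crop_to_width`` restores the nominal-width convention).
* Each k-means repetition uses k-means++-style seeding adapted to the L1
  distance; the repetition with the lowest total cityblock cost wins, and
  states are re-indexed in descending order of overall occupancy so state
  labels are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .sfnc import fisher_z
from .stats import GroupTestResult, bh_fdr, two_sample_t
from .types import ComponentTimecourses, StateModel, WindowedFNC, pair_labels

__all__ = ["TaperWindow", "build_taper", "windowed_fnc", "kmeans_states",
           "elbow_select_k", "state_group_contrast"]

log = logging.getLogger(__name__)


@dataclass
class TaperWindow:
    """Sliding-window taper: nonnegative weights, symmetric about center."""

    weights: np.ndarray
    nominal_width: int
    sigma: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("taper weights must be nonnegative")
        if self.weights.max() <= 0:
            raise ValueError("taper must have positive mass")
        if not np.allclose(self.weights, self.weights[::-1], atol=1e-12):
            raise ValueError("taper must be symmetric about its center")

    @property
    def length(self) -> int:
        return self.weights.size


def build_taper(width: int = 30, sigma: float = 3.0,
                support_halfwidth: int | None = None,
                crop_to_width: bool = False) -> TaperWindow:
    """Rectangle of ``width`` TRs convolved with a truncated Gaussian.

    The Gaussian kernel has standard deviation ``sigma`` (in TRs) and is
    truncated at ``+-support_halfwidth`` samples (default round(3*sigma))
    then normalized to unit mass, so the taper's weights sum to ``width``
    up to the <=1% mass lost to truncation.  ``sigma=0`` degenerates to the
    pure rectangle.  With ``crop_to_width`` the result is cut back to the
    central ``width`` samples.
    """
    if width < 2:
        raise ValueError("width must be at least 2 TRs")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rect = np.ones(width)
    if sigma == 0:
        return TaperWindow(rect, width, sigma)
    h = int(round(3 * sigma)) if support_halfwidth is None else int(support_halfwidth)
    offsets = np.arange(-h, h + 1)
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    kernel /= kernel.sum()
    weights = np.convolve(rect, kernel, mode="full")  # length width + 2h
    if crop_to_width:
        weights = weights[h:h + width]
    return TaperWindow(weights, width, sigma)


def _weighted_corr_vector(X: np.ndarray, w: np.ndarray,
                          iu: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Weighted Pearson correlations of all column pairs; upper triangle."""
    wsum = w.sum()
    mu = (w[:, None] * X).sum(axis=0) / wsum
    Xc = X - mu
    cov = (Xc * w[:, None]).T @ Xc / wsum
    var = np.diag(cov).copy()
    dead = var <= 0
    var[dead] = 1.0
    denom = np.sqrt(np.outer(var, var))
    r = cov / denom
    if dead.any():
        r[dead, :] = 0.0
        r[:, dead] = 0.0
        log.warning("zero weighted variance in a window; pairs set to 0")
    np.fill_diagonal(r, 0.0)
    return np.clip(r[iu], -1.0, 1.0)


def windowed_fnc(tc: ComponentTimecourses, taper: TaperWindow,
                 step: int = 1, fisher: bool = True) -> WindowedFNC:
    """Sliding tapered-window connectivity for one subject.

    Window w covers samples ``[s, s+L)`` with ``s = w*step``; each entry is
    the Fisher z of the taper-weighted Pearson correlation of a component
    pair (weighted means and variances).  ``fisher=False`` returns raw
    correlations.
    """
    L = taper.length
    T = tc.n_timepoints
    if T < L:
        raise ValueError(f"series length {T} shorter than window length {L}")
    starts = np.arange(0, T - L + 1, step)
    C = tc.n_components
    iu = np.triu_indices(C, k=1)
    rows = np.empty((starts.size, C * (C - 1) // 2))
    for wi, s in enumerate(starts):
        rows[wi] = _weighted_corr_vector(tc.data[s:s + L], taper.weights, iu)
    if fisher:
        rows = fisher_z(rows)
    return WindowedFNC(subject_id=tc.subject_id, windows=rows,
                       window_starts=starts,
                       component_labels=list(tc.component_labels))


# ---------------------------------------------------------------------------
# cityblock k-means (k-medians)

def _l1_kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding under the L1 distance."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d = cdist(X, centers[:1], metric="cityblock").ravel()
    for j in range(1, k):
        total = d.sum()
        if total <= 0:
            centers[j] = X[rng.integers(n)]
        else:
            centers[j] = X[rng.choice(n, p=d / total)]
        d = np.minimum(d, cdist(X, centers[j:j + 1], metric="cityblock").ravel())
    return centers


def _lloyd_l1(X: np.ndarray, centers: np.ndarray, max_iter: int
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd alternation with L1 assignment and componentwise-median update."""
    k = centers.shape[0]
    labels = np.full(X.shape[0], -1)
    for _ in range(max_iter):
        D = cdist(X, centers, metric="cityblock")
        new_labels = D.argmin(axis=1)
        # repair empty clusters: split the largest cluster at its farthest member
        for j in range(k):
            if not np.any(new_labels == j):
                counts = np.bincount(new_labels, minlength=k)
                big = counts.argmax()
                members = np.flatnonzero(new_labels == big)
                far = members[D[members, big].argmax()]
                new_labels[far] = j
                centers[j] = X[far]
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            centers[j] = np.median(X[labels == j], axis=0)
    D = cdist(X, centers, metric="cityblock")
    labels = D.argmin(axis=1)
    cost = float(D[np.arange(X.shape[0]), labels].sum())
    return centers, labels, cost


def kmeans_states(windowed: dict[str, WindowedFNC] | list[WindowedFNC],
                  k: int = 4, reps: int = 150, max_iter: int = 500,
                  seed: int = 0) -> StateModel:
    """Cluster all subjects' windowed FNC vectors into k recurring states.

    Best-of-``reps`` restarts of L1 Lloyd iteration; the winning model's
    states are re-indexed 1..k in descending order of overall occupancy.
    """
    if isinstance(windowed, dict):
        items = list(windowed.items())
    else:
        items = [(w.subject_id, w) for w in windowed]
    X = np.vstack([w.windows for _, w in items])
    if X.shape[0] < k:
        raise ValueError(f"{X.shape[0]} windows cannot form {k} clusters")
    # canonical row order makes the whole procedure invariant to subject
    # ordering and window shuffling: seeding sees the same matrix either way
    Xs = X[np.lexsort(X.T)]
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(reps)
    best = None
    costs = []
    for r in range(reps):
        rng = np.random.default_rng(rep_seeds[r])
        centers = _l1_kmeanspp_init(Xs, k, rng)
        centers, _, cost = _lloyd_l1(Xs, centers.copy(), max_iter)
        costs.append(cost)
        if best is None or cost < best[1]:
            best = (centers, cost)
    centers, cost = best
    D = cdist(X, centers, metric="cityblock")
    labels = D.argmin(axis=1)
    # deterministic state indexing: descending occupancy (ties by first use)
    occ = np.bincount(labels, minlength=k)
    order = np.argsort(-occ, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[labels]
    centers = centers[order]
    assignments = {}
    pos = 0
    for sid, w in items:
        assignments[sid] = labels[pos:pos + w.n_windows].copy()
        pos += w.n_windows
    return StateModel(k=k, centroids=centers, assignments=assignments,
                      distance="cityblock", replicate_costs=costs, seed=seed,
                      pair_labels=items[0][1].pair_labels)


def elbow_select_k(windowed, k_range=range(2, 9), reps: int = 10,
                   max_iter: int = 500, seed: int = 0
                   ) -> tuple[int, pd.DataFrame]:
    """Choose k at the elbow of the within/between dispersion-ratio curve.

    For each k the ratio of total within-cluster to between-cluster
    cityblock dispersion is recorded; the selected k is the curve's elbow,
    the point at maximal vertical distance below the chord joining the
    curve's endpoints.  (The second difference of the curve is also
    reported; as a selector it is dominated by the initial drop whenever
    cluster occupancies are unequal, which they are in resting-state
    data.)  At least three k values are required for an elbow to exist.
    """
    ks = sorted(k_range)
    if len(ks) < 3:
        raise ValueError("need at least 3 candidate k values for an elbow")
    if isinstance(windowed, dict):
        items = list(windowed.items())
    else:
        items = [(w.subject_id, w) for w in windowed]
    X = np.vstack([w.windows for _, w in items])
    overall = np.median(X, axis=0)
    ratios = []
    for k in ks:
        model = kmeans_states(windowed, k=k, reps=reps, max_iter=max_iter,
                              seed=seed + k)
        within = model.best_cost
        labels = np.concatenate([model.assignments[sid] for sid, _ in items])
        between = 0.0
        for j in range(1, k + 1):
            nj = int(np.sum(labels == j))
            between += nj * float(np.abs(model.centroids[j - 1] - overall).sum())
        if between <= 0:
            raise ValueError("degenerate input: no between-cluster dispersion")
        ratios.append(within / between)
    curve = pd.DataFrame({"k": ks, "wb_ratio": ratios})
    r = np.asarray(ratios)
    ka = np.asarray(ks, float)
    chord = r[0] + (r[-1] - r[0]) * (ka - ka[0]) / (ka[-1] - ka[0])
    gap = chord - r
    k_selected = int(ks[int(gap.argmax())])
    curve["elbow_gap"] = gap
    curve["curvature"] = np.concatenate([[np.nan], r[:-2] - 2 * r[1:-1] + r[2:],
                                         [np.nan]])
    return k_selected, curve


# ---------------------------------------------------------------------------
# per-state group contrast

def state_group_contrast(model: StateModel,
                         windowed: dict[str, WindowedFNC],
                         clinical: pd.DataFrame,
                         alpha: float = 0.05
                         ) -> dict[int, list[GroupTestResult]]:
    """Two-sample t-tests of per-state mean connectivity, FDR within state.

    Each subject contributes, per state, the mean of its window vectors
    assigned to that state; subjects with no windows in a state are
    excluded from that state's tests.  States with fewer than two subjects
    in either group are skipped with a warning.
    """
    clin = clinical.set_index("subject_id")
    out: dict[int, list[GroupTestResult]] = {}
    plabels = model.pair_labels
    for j in range(1, model.k + 1):
        pat_rows, ctl_rows = [], []
        excluded = 0
        for sid, w in windowed.items():
            mask = model.assignments[sid] == j
            if not mask.any():
                excluded += 1
                continue
            vec = w.windows[mask].mean(axis=0)
            (pat_rows if clin.loc[sid, "group"] == "PACG" else ctl_rows).append(vec)
        if excluded:
            log.info("state %d: %d subject(s) excluded (no windows)", j, excluded)
        if len(pat_rows) < 2 or len(ctl_rows) < 2:
            log.warning("state %d skipped: <2 subjects in a group", j)
            continue
        P = np.vstack(pat_rows)
        Cn = np.vstack(ctl_rows)
        results = []
        pvals = []
        for u in range(P.shape[1]):
            t, df, p = two_sample_t(P[:, u], Cn[:, u])
            results.append((plabels[u], float(P[:, u].mean() - Cn[:, u].mean()),
                            t, df, p))
            pvals.append(p)
        adj = bh_fdr(np.asarray(pvals))
        out[j] = [
            GroupTestResult(unit_label=lab, estimate=est, t_stat=t, df=df,
                            p=p, p_fdr=float(a), significant=bool(a < alpha))
            for (lab, est, t, df, p), a in zip(results, adj)
        ]
    return out
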