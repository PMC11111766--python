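"""Dynamic FNC: taper construction, windowed correlation, L1 k-means, elbow."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from netstates import dfnc
from netstates.dfnc import (build_taper, elbow_select_k, kmeans_states,
                            state_group_contrast, windowed_fnc)
from netstates.sfnc import compute_sfnc
from netstates.types import WindowedFNC
from tests.conftest import make_tc


class TestTaper:
    def test_sigma_zero_is_pure_rectangle(self):
        t = build_taper(width=30, sigma=0)
        assert t.length == 30
        assert np.array_equal(t.weights, np.ones(30))

    def test_default_taper_shape(self):
        t = build_taper(width=30, sigma=3)
        assert t.length == 48  # 30 + 2 * round(3 sigma)
        assert np.allclose(t.weights, t.weights[::-1])
        assert t.weights[t.length // 2] > 0.99       # plateau ~ 1
        assert t.weights[0] < 0.01                   # edges ~ 0
        assert abs(t.weights.sum() - 30) < 0.01 * 30  # mass preserved to 1%

    def test_reversal_symmetry(self):
        t = build_taper(width=20, sigma=2.5)
        assert np.allclose(t.weights, t.weights[::-1], atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_taper(width=1)
        with pytest.raises(ValueError):
            build_taper(width=10, sigma=-1)


class TestWindowedFnc:
    def test_window_count(self, rng):
        tc = make_tc(rng.normal(size=(230, 3)))
        w = windowed_fnc(tc, build_taper(30, sigma=0), step=1)
        assert w.n_windows == 201  # 230 - 30 + 1
        assert np.array_equal(w.window_starts, np.arange(201))

    def test_uniform_taper_equals_plain_correlation(self, rng):
        tc = make_tc(rng.normal(size=(60, 4)))
        w = windowed_fnc(tc, build_taper(30, sigma=0), fisher=False)
        iu = np.triu_indices(4, 1)
        for wi, s in enumerate(w.window_starts):
            r_ref = np.corrcoef(tc.data[s:s + 30], rowvar=False)[iu]
            assert np.allclose(w.windows[wi], r_ref, atol=1e-12)

    def test_stationary_series_windows_match_static(self, rng):
        # constant correlation structure: windowed z scatter around the
        # static z within a few Monte-Carlo standard deviations
        cov = np.array([[1, 0.6], [0.6, 1.0]])
        data = rng.multivariate_normal([0, 0], cov, size=500)
        tc = make_tc(data)
        taper = build_taper(30, sigma=3)
        w = windowed_fnc(tc, taper)
        static = compute_sfnc(tc).values[0, 1]
        ess = taper.weights.sum() ** 2 / (taper.weights ** 2).sum()
        sd = 1 / np.sqrt(ess - 3)
        assert abs(w.windows[:, 0].mean() - static) < 4 * sd / np.sqrt(10)

    def test_series_shorter_than_window_errors(self, rng):
        tc = make_tc(rng.normal(size=(20, 2)))
        with pytest.raises(ValueError):
            windowed_fnc(tc, build_taper(30, sigma=0))


def _windowed_from_array(X, sid="s"):
    C = 3  # P = 3 pairs
    return WindowedFNC(subject_id=sid, windows=X,
                       window_starts=np.arange(len(X)),
                       component_labels=[f"IC{i}" for i in range(C)])


class TestKmeans:
    def test_exact_clusters_recovered_with_zero_cost(self, rng):
        pts = rng.normal(size=(4, 3)) * 5
        X = np.repeat(pts, 10, axis=0)
        model = kmeans_states([_windowed_from_array(X)], k=4, reps=5, seed=0)
        assert model.best_cost == pytest.approx(0.0, abs=1e-12)

    def test_planted_partition_perfect_ari(self, rng):
        c1, c2 = np.zeros(3), np.full(3, 10 / 3)  # L1 separation 10
        labels = rng.integers(0, 2, size=200)
        X = np.where(labels[:, None] == 0, c1, c2) + rng.normal(0, 0.1, (200, 3))
        model = kmeans_states([_windowed_from_array(X)], k=2, reps=10, seed=1)
        pred = model.assignments["s"]
        assert adjusted_rand_score(labels, pred) == 1.0

    def test_more_reps_never_worse(self, rng):
        X = rng.normal(size=(150, 3))
        w = [_windowed_from_array(X)]
        cost_small = kmeans_states(w, k=3, reps=5, seed=3).best_cost
        cost_big = kmeans_states(w, k=3, reps=10, seed=3).best_cost
        assert cost_big <= cost_small + 1e-12

    def test_deterministic_under_fixed_seed(self, rng):
        X = rng.normal(size=(100, 3))
        w = [_windowed_from_array(X)]
        m1 = kmeans_states(w, k=3, reps=8, seed=9)
        m2 = kmeans_states(w, k=3, reps=8, seed=9)
        assert np.array_equal(m1.centroids, m2.centroids)
        assert np.array_equal(m1.assignments["s"], m2.assignments["s"])

    def test_subject_order_invariance(self, rng):
        X1, X2 = rng.normal(size=(60, 3)), rng.normal(size=(70, 3))
        wa = [_windowed_from_array(X1, "a"), _windowed_from_array(X2, "b")]
        wb = list(reversed(wa))
        ma = kmeans_states(wa, k=3, reps=40, seed=5)
        mb = kmeans_states(wb, k=3, reps=40, seed=5)
        assert ma.best_cost == pytest.approx(mb.best_cost, rel=1e-6)

    def test_centroids_are_member_medians(self, rng):
        X = rng.normal(size=(200, 3))
        w = [_windowed_from_array(X)]
        model = kmeans_states(w, k=3, reps=10, seed=2)
        lab = model.assignments["s"]
        for j in range(1, 4):
            med = np.median(X[lab == j], axis=0)
            assert np.allclose(model.centroids[j - 1], med, atol=1e-10)

    def test_states_ordered_by_occupancy(self, rng):
        X = np.vstack([np.zeros((100, 3)), np.full((30, 3), 5.0)])
        X += rng.normal(0, 0.05, X.shape)
        model = kmeans_states([_windowed_from_array(X)], k=2, reps=5, seed=0)
        occ = [np.mean(model.assignments["s"] == j) for j in (1, 2)]
        assert occ[0] >= occ[1]

    def test_k_exceeding_windows_errors(self, rng):
        X = rng.normal(size=(3, 3))
        with pytest.raises(ValueError):
            kmeans_states([_windowed_from_array(X)], k=5, reps=2, seed=0)


class TestElbow:
    def test_planted_four_states_selected(self, rng):
        centers = rng.normal(size=(4, 3)) * 6
        labels = rng.integers(0, 4, size=400)
        X = centers[labels] + rng.normal(0, 0.3, (400, 3))
        k, curve = elbow_select_k([_windowed_from_array(X)],
                                  range(2, 9), reps=5, seed=4)
        assert k == 4
        # curve monotone non-increasing within replicate noise
        r = curve["wb_ratio"].to_numpy()
        assert np.all(np.diff(r) <= 0.01 * r[:-1])

    def test_too_few_k_values_error(self, rng):
        X = rng.normal(size=(50, 3))
        with pytest.raises(ValueError):
            elbow_select_k([_windowed_from_array(X)], [2, 3], seed=0)


class TestStateContrast:
    def _setup(self, rng, planted_state=None, shift=-0.6):
        """Directly constructed windows and assignments for two groups."""
        k = 3
        centers = rng.normal(size=(k, 3))
        windowed, rows = {}, []
        assignments = {}
        for i in range(24):
            group = "PACG" if i < 12 else "HC"
            sid = f"S{i:02d}"
            lab = rng.integers(1, k + 1, size=40)
            X = centers[lab - 1] + rng.normal(0, 0.2, (40, 3))
            if group == "PACG" and planted_state:
                X[lab == planted_state, 1] += shift
            windowed[sid] = _windowed_from_array(X, sid)
            assignments[sid] = lab
            rows.append({"subject_id": sid, "group": group, "age": 50.0,
                         "sex": "M", "education": 12.0})
        from netstates.types import StateModel
        model = StateModel(k=k, centroids=centers, assignments=assignments,
                           distance="cityblock", replicate_costs=[0.0],
                           seed=0, pair_labels=windowed["S00"].pair_labels)
        return model, windowed, pd.DataFrame(rows)

    def test_planted_drop_flagged_in_right_state(self, rng):
        hits, false_hits = 0, 0
        n_rep = 25
        for _ in range(n_rep):
            model, windowed, clin = self._setup(rng, planted_state=2)
            res = state_group_contrast(model, windowed, clin)
            hits += res[2][1].significant
            false_hits += any(r.significant for r in res[1]) \
                + any(r.significant for r in res[3])
        assert hits / n_rep >= 0.8
        assert false_hits / (2 * n_rep) < 0.15

    def test_null_calibration(self, rng):
        fractions = []
        for _ in range(100):
            model, windowed, clin = self._setup(rng, planted_state=None)
            res = state_group_contrast(model, windowed, clin)
            sig = [r.significant for lst in res.values() for r in lst]
            fractions.append(np.mean(sig))
        assert np.mean(fractions) <= 0.05 + 2 * np.std(fractions) / 10

    def test_missing_state_subject_excluded(self, rng):
        model, windowed, clin = self._setup(rng)
        # subject S00 never visits state 3
        model.assignments["S00"][model.assignments["S00"] == 3] = 1
        res = state_group_contrast(model, windowed, clin)
        assert set(res) == {1, 2, 3}  # still enough subjects everywhere


class TestStaticDynamicConsistency:
    def test_full_length_rectangle_equals_static(self, rng):
        tc = make_tc(rng.normal(size=(80, 4)))
        taper = build_taper(width=80, sigma=0)
        w = windowed_fnc(tc, taper)
        assert w.n_windows == 1
        static = compute_sfnc(tc)
        assert np.allclose(w.windows[0], static.upper(), atol=1e-10)

    def test_tapered_full_window_matches_weighted_oracle(self, rng):
        tc = make_tc(rng.normal(size=(100, 4)))
        taper = build_taper(width=100 - 18, sigma=3)  # L = 100
        assert taper.length == 100
        w = windowed_fnc(tc, taper, fisher=False)
        wts = taper.weights / taper.weights.sum()
        X = tc.data
        mu = wts @ X
        Xc = X - mu
        cov = np.einsum("t,ti,tj->ij", wts, Xc, Xc)
        d = np.sqrt(np.diag(cov))
        r_oracle = (cov / np.outer(d, d))[np.triu_indices(4, 1)]
        assert np.allclose(w.windows[0], r_oracle, atol=1e-10)
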