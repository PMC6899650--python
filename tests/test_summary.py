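"""Summary-function estimators against independent brute-force oracles."""

import numpy as np
import pytest

from sppa import (
    DistanceGrid,
    ObservationWindow,
    estimate_L,
    estimate_nn,
    estimate_oring,
    estimate_pcf,
    estimate_pcf_bivariate,
    simulate_csr,
)
from sppa.errors import UndefinedCurveError
from sppa.summary import moving_average


# ---------------------------------------------------------------------------
# Brute-force double-loop oracles (independent of the vectorised estimators)
# ---------------------------------------------------------------------------


def rect_translation_area(window, dx, dy):
    x0, y0, x1, y1 = window.bounds
    return max((x1 - x0) - abs(dx), 0.0) * max((y1 - y0) - abs(dy), 0.0)


def brute_pcf(pts, window, grid):
    r = grid.r_values
    h = grid.bandwidth
    n = len(pts)
    sums = np.zeros(len(r))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dx, dy = pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1]
            d = np.hypot(dx, dy)
            k = int(d // h)
            if k < len(r):
                sums[k] += 1.0 / rect_translation_area(window, dx, dy)
    lam2 = n * (n - 1) / window.area**2
    g = sums / (2 * np.pi * r * h * lam2)
    return moving_average(g, grid.smoothing_span)


def brute_cross_pcf(pts_a, pts_b, window, grid):
    r = grid.r_values
    h = grid.bandwidth
    sums = np.zeros(len(r))
    for a in pts_a:
        for b in pts_b:
            dx, dy = a[0] - b[0], a[1] - b[1]
            d = np.hypot(dx, dy)
            if d == 0:
                continue
            k = int(d // h)
            if k < len(r):
                sums[k] += 1.0 / rect_translation_area(window, dx, dy)
    lam2 = len(pts_a) * len(pts_b) / window.area**2
    g = sums / (2 * np.pi * r * h * lam2)
    return moving_average(g, grid.smoothing_span)


def brute_K(pts, window, grid):
    r = grid.r_values
    n = len(pts)
    K = np.zeros(len(r))
    for k, rv in enumerate(r):
        s = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                dx, dy = pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1]
                if np.hypot(dx, dy) <= rv:
                    s += 1.0 / rect_translation_area(window, dx, dy)
        K[k] = s / (n * (n - 1) / window.area**2)
    return K


def brute_nn(pts, window, grid):
    n = len(pts)
    d_nn = np.full(n, np.inf)
    for i in range(n):
        for j in range(n):
            if i != j:
                d_nn[i] = min(d_nn[i], float(np.hypot(*(pts[i] - pts[j]))))
    x0, y0, x1, y1 = window.bounds
    b = np.array([min(p[0] - x0, x1 - p[0], p[1] - y0, y1 - p[1]) for p in pts])
    D = []
    last = 0.0
    for rv in grid.r_values:
        denom = int((b >= rv).sum())
        if denom:
            last = sum(1 for i in range(n) if d_nn[i] <= rv and b[i] >= rv) / denom
        D.append(last)
    return np.maximum.accumulate(np.clip(D, 0, 1))


# ---------------------------------------------------------------------------
# Equivalence with oracles (1e-10)
# ---------------------------------------------------------------------------


@pytest.fixture
def fixed_pattern(rng, big_window):
    return big_window.sample_uniform(40, rng)


class TestBruteForceEquivalence:
    grid = DistanceGrid(0.25, 2.0, 3)

    def test_pcf(self, fixed_pattern, big_window):
        est = estimate_pcf(fixed_pattern, big_window, self.grid)
        oracle = brute_pcf(fixed_pattern, big_window, self.grid)
        assert np.max(np.abs(est.values - oracle)) < 1e-10

    def test_pcf_five_points(self, unit_window):
        pts = np.array([[0.2, 0.2], [0.8, 0.3], [0.5, 0.5], [0.3, 0.7], [0.7, 0.8]])
        grid = DistanceGrid(0.1, 0.25, 1)
        est = estimate_pcf(pts, unit_window, grid)
        assert np.max(np.abs(est.values - brute_pcf(pts, unit_window, grid))) < 1e-10

    def test_cross_pcf(self, rng, big_window):
        a = big_window.sample_uniform(3, rng)
        b = big_window.sample_uniform(3, rng)
        grid = DistanceGrid(0.5, 2.0, 1)
        est = estimate_pcf_bivariate(a, b, big_window, grid)
        assert np.max(np.abs(est.values - brute_cross_pcf(a, b, big_window, grid))) < 1e-10

    def test_K_and_L(self, rng, big_window):
        pts = big_window.sample_uniform(10, rng)
        grid = DistanceGrid(0.25, 2.0, 1)
        est = estimate_L(pts, big_window, grid)
        oracle_L = np.sqrt(brute_K(pts, big_window, grid) / np.pi)
        assert np.max(np.abs(est.values - oracle_L)) < 1e-10

    def test_oring_is_lambda_g(self, fixed_pattern, big_window):
        g = estimate_pcf(fixed_pattern, big_window, self.grid)
        o = estimate_oring(fixed_pattern, big_window, self.grid)
        lam = len(fixed_pattern) / big_window.area
        assert np.max(np.abs(o.values - lam * g.values)) < 1e-12

    def test_oring_two_points(self, big_window):
        pts = np.array([[4.0, 5.0], [4.5, 5.0]])
        grid = DistanceGrid(0.2, 1.0, 1)
        o = estimate_oring(pts, big_window, grid)
        oracle = (2 / big_window.area) * brute_pcf(pts, big_window, grid)
        assert np.max(np.abs(o.values - oracle)) < 1e-10

    def test_nn(self, rng, big_window):
        pts = big_window.sample_uniform(20, rng)
        grid = DistanceGrid(0.25, 3.0, 1)
        est = estimate_nn(pts, big_window, grid)
        assert np.max(np.abs(est.values - brute_nn(pts, big_window, grid))) < 1e-10


class TestGeometryCases:
    def test_two_point_peak(self):
        w = ObservationWindow.rectangle(0, 0, 10, 10)
        pts = np.array([[4.0, 5.0], [4.5, 5.0]])
        g = estimate_pcf(pts, w, DistanceGrid(0.1, 1.0, 1))
        peak = g.r[np.argmax(g.values)]
        assert peak == pytest.approx(0.5, abs=0.051)
        far = g.values[np.abs(g.r - 0.5) > 0.15]
        assert np.all(far == 0)

    def test_cross_pcf_displaced_copy_peak(self, rng):
        w = ObservationWindow.rectangle(0, 0, 10, 10)
        a = ObservationWindow.rectangle(0.5, 0.5, 9.0, 9.0).sample_uniform(150, rng)
        b = a + np.array([0.3, 0.0])
        g = estimate_pcf_bivariate(a, b, w, DistanceGrid(0.05, 1.0, 1))
        assert g.r[np.argmax(g.values)] == pytest.approx(0.3, abs=0.051)

    def test_lattice_nn_jump(self):
        xs, ys = np.meshgrid(np.arange(10), np.arange(10))
        pts = np.column_stack([xs.ravel() + 0.5, ys.ravel() + 0.5]).astype(float)
        w = ObservationWindow.rectangle(0, 0, 10, 10)
        d = estimate_nn(pts, w, DistanceGrid(0.25, 2.0, 1))
        assert np.all(d.values[d.r < 1.0] == 0)
        assert np.all(d.values[d.r >= 1.0] == 1)

    def test_undefined_below_two_points(self, unit_window):
        with pytest.raises(UndefinedCurveError):
            estimate_pcf(np.array([[0.5, 0.5]]), unit_window)
        with pytest.raises(UndefinedCurveError):
            estimate_pcf_bivariate(np.empty((0, 2)), np.array([[0.5, 0.5]]), unit_window)

    def test_r_max_warning(self, unit_window):
        pts = np.array([[0.2, 0.2], [0.8, 0.8]])
        with pytest.warns(UserWarning, match="quarter"):
            estimate_pcf(pts, unit_window, DistanceGrid(0.1, 0.9, 1))


class TestCalibration:
    """CSR closed-form expectations (reduced replicate counts)."""

    def test_csr_mean_g_near_one(self):
        w = ObservationWindow.rectangle(0, 0, 10, 10)
        grid = DistanceGrid(0.1, 2.5, 3)
        means = []
        for s in range(15):
            g = estimate_pcf(simulate_csr(w, n=1000, seed=s), w, grid)
            sel = (g.r >= 0.2) & (g.r <= 2.5)
            means.append(g.values[sel].mean())
        assert np.mean(means) == pytest.approx(1.0, abs=0.05)

    def test_csr_L_matches_r(self):
        w = ObservationWindow.rectangle(0, 0, 10, 10)
        grid = DistanceGrid(0.1, 2.0, 1)
        devs = []
        for s in range(5):
            L = estimate_L(simulate_csr(w, n=2000, seed=s), w, grid)
            devs.append(np.max(np.abs(L.values - L.r)))
        assert np.mean(devs) <= 0.05

    def test_csr_oring_near_lambda(self):
        w = ObservationWindow.rectangle(0, 0, 10, 10)
        vals = []
        for s in range(10):
            o = estimate_oring(simulate_csr(w, n=1000, seed=s), w, DistanceGrid(0.1, 2.0, 3))
            vals.append(o.values[o.r >= 0.2].mean())
        assert np.mean(vals) == pytest.approx(10.0, rel=0.03)

    def test_csr_nn_closed_form(self):
        # D(r) = 1 - exp(-lambda pi r^2) under CSR
        w = ObservationWindow.rectangle(0, 0, 10, 10)
        lam = 10.0
        grid = DistanceGrid(0.02, 0.6, 1)
        curves = [
            estimate_nn(simulate_csr(w, n=1000, seed=s), w, grid).values for s in range(20)
        ]
        expected = 1 - np.exp(-lam * np.pi * grid.r_values**2)
        assert np.max(np.abs(np.mean(curves, axis=0) - expected)) <= 0.05


class TestInvariances:
    def test_smoothing_span_one_is_identity(self, rng, big_window):
        pts = big_window.sample_uniform(60, rng)
        g1 = estimate_pcf(pts, big_window, DistanceGrid(0.2, 2.0, 1))
        g3 = estimate_pcf(pts, big_window, DistanceGrid(0.2, 2.0, 3))
        assert np.max(np.abs(moving_average(g1.values, 3) - g3.values)) < 1e-12

    def test_rigid_motion_invariance(self, rng):
        w = ObservationWindow.rectangle(0, 0, 8, 6)
        pts = w.sample_uniform(40, rng)
        grid = DistanceGrid(0.25, 1.5, 3)
        base = estimate_pcf(pts, w, grid)
        # translation
        shift = np.array([3.0, -2.0])
        w_t = ObservationWindow.rectangle(3, -2, 11, 4)
        g_t = estimate_pcf(pts + shift, w_t, grid)
        assert np.allclose(g_t.values, base.values, atol=1e-10)
        # rotation by 30 degrees (window becomes a general polygon)
        th = np.radians(30)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        w_r = w.transformed(R)
        g_r = estimate_pcf(pts @ R.T, w_r, grid)
        assert np.allclose(g_r.values, base.values, rtol=1e-6, atol=1e-8)
        L_r = estimate_L(pts @ R.T, w_r, grid)
        L0 = estimate_L(pts, w, grid)
        assert np.allclose(L_r.values, L0.values, rtol=1e-6, atol=1e-8)
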