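"""Thomas-family closed forms, simulators, minimal contrast and the ladder."""

import numpy as np
import pytest
from scipy.stats import kstest

from sppa import (
    AnalysisConfig,
    DistanceGrid,
    DoubleThomasParams,
    ObservationWindow,
    SummaryCurve,
    ThomasParams,
    estimate_L,
    estimate_pcf,
    fit_minimal_contrast,
    fit_protocol,
    mean_cluster_size,
    simulate_double_thomas,
    simulate_inhibition,
    simulate_inhom_thomas,
    simulate_thomas,
    thomas_L,
    thomas_pcf,
)
from sppa.errors import InsufficientDataError, NoAggregationError
from sppa.nullmodels import CallableIntensity, ConstantIntensity


class TestClosedForms:
    def test_value_at_zero(self):
        p = ThomasParams(sigma=0.1, rho=1.0, lambda_total=10.0)
        assert thomas_pcf(p, 0.0) == pytest.approx(1 + 1 / (4 * np.pi * 0.01), rel=1e-12)

    def test_asymptote(self):
        p = ThomasParams(0.1, 1.0, 10.0)
        assert thomas_pcf(p, 100.0) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_r_and_rho(self):
        # restrict to the range where the exponential has not underflowed
        r = np.linspace(0.01, 0.8, 50)
        g1 = thomas_pcf(ThomasParams(0.1, 1.0, 10.0), r)
        assert np.all(np.diff(g1) < 0)
        g2 = thomas_pcf(ThomasParams(0.1, 2.0, 10.0), r)
        assert np.all(g2 < g1)
        # excess scales as 1/rho
        assert np.allclose((g1 - 1) / (g2 - 1), 2.0, rtol=1e-12)

    def test_mean_cluster_size(self):
        assert mean_cluster_size(ThomasParams(0.1, 3.0, 3.0)) == pytest.approx(1.0)
        # arithmetic convention of the summary table: lambda / rho
        assert mean_cluster_size(ThomasParams(0.1, 3.11, 36.83)) == pytest.approx(
            11.842, abs=5e-3
        )

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            ThomasParams(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            DoubleThomasParams(ThomasParams(0.1, 1, 1), -0.1, 2.0)


class TestThomasSimulator:
    window = ObservationWindow.rectangle(0, 0, 10, 10)

    def test_zero_mu_empty(self):
        p = ThomasParams(0.1, 1.0, 1e-9)
        assert len(simulate_thomas(p, self.window, seed=0)) <= 1

    def test_intensity_identity(self):
        # mean count = rho * mu * |W|
        p = ThomasParams(0.1, 1.0, 8.0)
        rng = np.random.default_rng(1)
        counts = [len(simulate_thomas(p, self.window, seed=rng)) for _ in range(150)]
        assert np.mean(counts) == pytest.approx(800, rel=0.05)

    def test_offspring_distance_rayleigh(self):
        # parent-to-offspring displacement radius ~ Rayleigh(sigma)
        rng = np.random.default_rng(2)
        sigma = 0.2
        parents = np.zeros((3000, 2))
        from sppa.clusters import _gaussian_offspring

        off = _gaussian_offspring(parents, 1.0, sigma, rng)
        # offspring inherit their parent's (origin) position here
        radii = np.hypot(off[:, 0], off[:, 1])
        stat = kstest(radii, "rayleigh", args=(0, sigma))
        assert stat.statistic <= 0.05

    def test_envelope_contains_closed_form(self):
        p = ThomasParams(0.1, 1.0, 10.0)
        w = ObservationWindow.rectangle(0, 0, 20, 20)
        grid = DistanceGrid(0.05, 1.0, 1)
        rng = np.random.default_rng(3)
        sims = np.array(
            [
                estimate_pcf(simulate_thomas(p, w, seed=rng), w, grid).values
                for _ in range(199)
            ]
        )
        lo, hi = np.sort(sims, axis=0)[9], np.sort(sims, axis=0)[189]
        sel = grid.r_values >= 0.05
        theo = thomas_pcf(p, grid.r_values)
        assert np.all(theo[sel] >= lo[sel]) and np.all(theo[sel] <= hi[sel])


class TestDoubleThomas:
    def test_count_chain(self):
        w = ObservationWindow.rectangle(0, 0, 10, 10)
        large = ThomasParams(sigma=0.5, rho=0.1, lambda_total=0.5)  # mu_large = 5
        p = DoubleThomasParams(large, small_sigma=0.05, small_mu=4.0)
        rng = np.random.default_rng(4)
        counts = [len(simulate_double_thomas(p, w, seed=rng)) for _ in range(150)]
        assert np.mean(counts) == pytest.approx(0.5 * 4.0 * 100, rel=0.05)

    def test_two_scale_pcf_excess(self):
        w = ObservationWindow.rectangle(0, 0, 20, 20)
        large = ThomasParams(0.6, 0.05, 0.4)
        p = DoubleThomasParams(large, small_sigma=0.05, small_mu=8.0)
        grid = DistanceGrid(0.05, 2.0, 1)
        rng = np.random.default_rng(5)
        gs = [
            estimate_pcf(simulate_double_thomas(p, w, seed=rng), w, grid).values
            for _ in range(30)
        ]
        gm = np.mean(gs, axis=0)
        r = grid.r_values
        g_small = gm[np.argmin(np.abs(r - p.small_sigma))]
        g_large2 = gm[np.argmin(np.abs(r - 2 * large.sigma))]
        assert g_small > g_large2 > 1.0

    def test_degenerate_nesting_reduces_to_thomas(self):
        # small_mu = 1, tiny small_sigma: same mean PCF as the outer Thomas
        w = ObservationWindow.rectangle(0, 0, 20, 20)
        large = ThomasParams(0.2, 0.5, 4.0)
        p = DoubleThomasParams(large, small_sigma=1e-4, small_mu=1.0)
        grid = DistanceGrid(0.1, 1.0, 1)
        rng = np.random.default_rng(6)
        g_d = np.mean(
            [estimate_pcf(simulate_double_thomas(p, w, seed=rng), w, grid).values
             for _ in range(60)], axis=0)
        g_t = np.mean(
            [estimate_pcf(simulate_thomas(large, w, seed=rng), w, grid).values
             for _ in range(60)], axis=0)
        # Poisson(1) nested counts leave coincident-point multiplicities, so
        # the sub-bandwidth bin differs; beyond it the curves agree
        assert np.max(np.abs(g_d[1:] - g_t[1:])) <= 0.5


class TestInhomThomas:
    window = ObservationWindow.rectangle(0, 0, 10, 10)

    def test_constant_surface_same_distribution(self):
        p = ThomasParams(0.1, 1.0, 6.0)
        rng = np.random.default_rng(7)
        n_thin = [
            len(simulate_inhom_thomas(p, ConstantIntensity(5.0), self.window, seed=rng))
            for _ in range(100)
        ]
        # uniform retention = 1 when surface is constant (ratio to max is 1)
        assert np.mean(n_thin) == pytest.approx(600, rel=0.1)

    def test_zero_surface_empty(self):
        p = ThomasParams(0.1, 1.0, 6.0)
        out = simulate_inhom_thomas(p, ConstantIntensity(0.0), self.window, seed=1)
        assert len(out) == 0

    def test_half_window_mask(self):
        p = ThomasParams(0.1, 1.0, 6.0)
        surf = CallableIntensity(lambda x, y: (x < 5.0).astype(float))
        pts = simulate_inhom_thomas(p, surf, self.window, seed=2)
        assert len(pts) > 0
        assert np.all(pts[:, 0] < 5.0)


class TestMinimalContrast:
    grid = DistanceGrid(0.1, 2.5, 1)

    def _exact_curves(self, p):
        r = self.grid.r_values
        g = SummaryCurve("pcf", r, thomas_pcf(p, r), 500, 0.1)
        L = SummaryCurve("L", r, thomas_L(p, r), 500, 0.1)
        return g, L

    def test_self_consistency_exact_input(self):
        p = ThomasParams(0.15, 2.0, 20.0)
        g, L = self._exact_curves(p)
        fit = fit_minimal_contrast(g, L, "TC", 20.0)
        assert fit.sigma == pytest.approx(0.15, abs=1e-4)
        assert fit.rho == pytest.approx(2.0, abs=1e-4)

    def test_flat_curve_raises(self):
        r = self.grid.r_values
        g = SummaryCurve("pcf", r, np.ones_like(r), 100, 0.1)
        with pytest.raises(NoAggregationError):
            fit_minimal_contrast(g, None, "TC", 1.0, fit_basis="pcf")

    def test_parameter_recovery_from_simulations(self):
        w = ObservationWindow.rectangle(0, 0, 10, 10)
        true = ThomasParams(0.1, 1.0, 10.0)
        errs = []
        for s in range(12):
            pts = simulate_thomas(true, w, seed=s)
            g = estimate_pcf(pts, w, self.grid)
            L = estimate_L(pts, w, self.grid)
            fit = fit_minimal_contrast(g, L, "TC", len(pts) / w.area)
            errs.append([abs(fit.sigma - 0.1) / 0.1, abs(fit.rho - 1.0)])
        med = np.median(errs, axis=0)
        assert med[0] <= 0.25 and med[1] <= 0.25

    def test_mu_recovery(self):
        w = ObservationWindow.rectangle(0, 0, 10, 10)
        true = ThomasParams(0.1, 1.0, 10.0)  # mu = 10
        mus = []
        for s in range(12):
            pts = simulate_thomas(true, w, seed=100 + s)
            g = estimate_pcf(pts, w, self.grid)
            L = estimate_L(pts, w, self.grid)
            fit = fit_minimal_contrast(g, L, "TC", len(pts) / w.area)
            mus.append(mean_cluster_size(fit))
        assert np.median(mus) == pytest.approx(10.0, rel=0.3)


class TestFitProtocol:
    window = ObservationWindow.rectangle(0, 0, 10, 10)
    config = AnalysisConfig(n_sims=99, r_max=1.2, min_n=30, hp_search_sims=49)

    def test_insufficient_data(self):
        from sppa import simulate_csr

        pts = simulate_csr(self.window, n=10, seed=0)
        with pytest.raises(InsufficientDataError):
            fit_protocol(pts, self.window, self.config, seed=1)

    def test_csr_recovered(self):
        from sppa import simulate_csr

        kinds = [
            fit_protocol(
                simulate_csr(self.window, n=300, seed=s), self.window, self.config,
                seed=100 + s,
            ).kind
            for s in range(10)
        ]
        assert kinds.count("CSR") >= 8

    def test_thomas_recovered_with_sigma(self):
        true = ThomasParams(0.1, 1.0, 8.0)
        hits = 0
        for s in range(6):
            pts = simulate_thomas(true, self.window, seed=s)
            fit = fit_protocol(pts, self.window, self.config, seed=200 + s)
            if fit.kind in ("TC", "DTC"):
                sigma = (
                    fit.params.sigma if fit.kind == "TC" else fit.params.small_sigma
                )
                if abs(sigma - 0.1) / 0.1 <= 0.3:
                    hits += 1
        assert hits >= 4

    def test_hardcore_is_segregated(self):
        pts = simulate_inhibition(self.window, 500, 0.2, seed=3)
        fit = fit_protocol(pts, self.window, self.config, seed=4)
        assert fit.kind == "SEGREGATED"

    def test_never_cluster_without_excursion_above(self):
        # a CSR pattern accepted at the first rung never reaches cluster fits
        from sppa import simulate_csr

        for s in range(5):
            fit = fit_protocol(
                simulate_csr(self.window, n=200, seed=50 + s), self.window,
                self.config, seed=60 + s,
            )
            if fit.kind in ("TC", "DTC", "ITC"):
                csr_env = fit.candidates["CSR"].envelope
                assert any(sign > 0 for *_, sign in csr_env.excursions)
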