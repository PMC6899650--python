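"""Thomas cluster process family: closed forms, simulators and fitting.

A Thomas cluster process (TC) models dispersal limitation: Poisson parent
points of density ρ, each spawning a Poisson(μ) number of offspring
displaced by an isotropic Gaussian of standard deviation σ per axis.  Its
pair correlation function has the closed form

    g(r) = 1 + exp(−r² / 4σ²) / (4π σ² ρ)

and Ripley's K is K(r) = πr² + (1 − exp(−r²/4σ²)) / ρ.  The double Thomas
process (DTC) nests a second Gaussian cluster scale inside the first; the
inhomogeneous Thomas process (ITC) thins a TC realisation by an intensity
surface, adding habitat filtering on top of dispersal limitation.

Fitting is by minimal contrast: squared discrepancy between observed and
model summary functions (g directly, K through the variance-stabilising
fourth-root transform), summed over the aggregated part of the distance
grid (the contiguous region where the observed g exceeds 1, excluding
sub-2-cm distances where the finite specimen size dominates).

:func:`fit_protocol` walks the model ladder used for each taxon: CSR, then
a heterogeneous Poisson background, then TC, DTC and ITC, scoring each rung
with Monte-Carlo envelopes and Diggle's goodness-of-fit on both the PCF and
the nearest-neighbour function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize

from .config import AnalysisConfig
from .errors import InsufficientDataError, NoAggregationError
from .geometry import ObservationWindow
from .nullmodels import (
    EnvelopeResult,
    GofResult,
    IntensitySurface,
    as_rng,
    diggle_gof,
    monte_carlo_envelope,
    moving_window_intensity,
    simulate_csr,
    simulate_heterogeneous_poisson,
)
from .summary import SummaryCurve, estimate_nn, estimate_pcf, estimate_L


# ---------------------------------------------------------------------------
# Parameters and closed forms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThomasParams:
    """Thomas process parameters: σ (m), ρ (parents·m⁻²), λ (points·m⁻²)."""

    sigma: float
    rho: float
    lambda_total: float

    def __post_init__(self):
        if self.sigma <= 0 or self.rho <= 0 or self.lambda_total <= 0:
            raise ValueError("sigma, rho and lambda_total must all be > 0")

    @property
    def mu(self) -> float:
        """Mean offspring per parent, λ/ρ."""
        return self.lambda_total / self.rho


@dataclass(frozen=True)
class DoubleThomasParams:
    """Nested (double) Thomas process.

    ``large`` describes the outer scale: grandparents of density
    ``large.rho`` spawn cluster centres with spread ``large.sigma``;
    ``large.lambda_total`` is the density of those centres.  Each centre
    then spawns Poisson(``small_mu``) points with spread ``small_sigma``,
    so the total intensity is ``large.lambda_total * small_mu``.
    """

    large: ThomasParams
    small_sigma: float
    small_mu: float

    def __post_init__(self):
        if self.small_sigma <= 0 or self.small_mu <= 0:
            raise ValueError("small_sigma and small_mu must be > 0")

    @property
    def lambda_total(self) -> float:
        return self.large.lambda_total * self.small_mu


def mean_cluster_size(params: ThomasParams) -> float:
    """Mean number of individuals per cluster, λ/ρ."""
    return params.lambda_total / params.rho


def thomas_pcf(params: ThomasParams, r) -> np.ndarray:
    """Closed-form Thomas pair correlation g(r) = 1 + e^{−r²/4σ²}/(4πσ²ρ)."""
    r = np.asarray(r, float)
    s2 = params.sigma**2
    return 1.0 + np.exp(-(r**2) / (4 * s2)) / (4 * np.pi * s2 * params.rho)


def thomas_K(params: ThomasParams, r) -> np.ndarray:
    r = np.asarray(r, float)
    return np.pi * r**2 + (1.0 - np.exp(-(r**2) / (4 * params.sigma**2))) / params.rho


def thomas_L(params: ThomasParams, r) -> np.ndarray:
    return np.sqrt(thomas_K(params, r) / np.pi)


def double_thomas_pcf(params: DoubleThomasParams, r) -> np.ndarray:
    """Closed-form PCF of the nested Thomas process (two Gaussian scales)."""
    r = np.asarray(r, float)
    ss2 = params.small_sigma**2
    se2 = params.large.sigma**2 + ss2  # same-grandparent pair spread
    kappa_p = params.large.lambda_total  # density of inner-cluster centres
    rho_g = params.large.rho
    return (
        1.0
        + np.exp(-(r**2) / (4 * ss2)) / (4 * np.pi * ss2 * kappa_p)
        + np.exp(-(r**2) / (4 * se2)) / (4 * np.pi * se2 * rho_g)
    )


def double_thomas_K(params: DoubleThomasParams, r) -> np.ndarray:
    r = np.asarray(r, float)
    ss2 = params.small_sigma**2
    se2 = params.large.sigma**2 + ss2
    return (
        np.pi * r**2
        + (1.0 - np.exp(-(r**2) / (4 * ss2))) / params.large.lambda_total
        + (1.0 - np.exp(-(r**2) / (4 * se2))) / params.large.rho
    )


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------


def _gaussian_offspring(
    parents: np.ndarray, mu: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    counts = rng.poisson(mu, len(parents))
    total = int(counts.sum())
    if total == 0:
        return np.empty((0, 2), float)
    centres = np.repeat(parents, counts, axis=0)
    return centres + rng.normal(0.0, sigma, (total, 2))


def simulate_thomas(
    params: ThomasParams, window: ObservationWindow, seed=None
) -> np.ndarray:
    """Simulate a Thomas process on the window (parents buffered by 4σ)."""
    rng = as_rng(seed)
    xmin, ymin, xmax, ymax = window.bounds
    pad = 4 * params.sigma
    area = (xmax - xmin + 2 * pad) * (ymax - ymin + 2 * pad)
    if params.rho * area * max(params.mu, 1.0) > 2e7:
        raise ValueError(
            f"implausible Thomas parameters (sigma={params.sigma:g}, "
            f"rho={params.rho:g}): expected point count exceeds 2e7"
        )
    n_parents = int(rng.poisson(params.rho * area))
    parents = np.column_stack(
        [
            rng.uniform(xmin - pad, xmax + pad, n_parents),
            rng.uniform(ymin - pad, ymax + pad, n_parents),
        ]
    )
    pts = _gaussian_offspring(parents, params.mu, params.sigma, rng)
    if len(pts) == 0:
        return pts
    return pts[window.contains(pts[:, 0], pts[:, 1])]


def simulate_double_thomas(
    params: DoubleThomasParams, window: ObservationWindow, seed=None
) -> np.ndarray:
    """Simulate the nested Thomas process: outer clusters of inner clusters."""
    rng = as_rng(seed)
    xmin, ymin, xmax, ymax = window.bounds
    pad = 4 * (params.large.sigma + params.small_sigma)
    area = (xmax - xmin + 2 * pad) * (ymax - ymin + 2 * pad)
    expected = params.large.rho * area * max(params.large.mu, 1.0) * max(params.small_mu, 1.0)
    if expected > 2e7:
        raise ValueError("implausible double-Thomas parameters: expected count exceeds 2e7")
    n_grand = int(rng.poisson(params.large.rho * area))
    grand = np.column_stack(
        [
            rng.uniform(xmin - pad, xmax + pad, n_grand),
            rng.uniform(ymin - pad, ymax + pad, n_grand),
        ]
    )
    centres = _gaussian_offspring(grand, params.large.mu, params.large.sigma, rng)
    pts = _gaussian_offspring(centres, params.small_mu, params.small_sigma, rng)
    if len(pts) == 0:
        return pts
    return pts[window.contains(pts[:, 0], pts[:, 1])]


def simulate_inhom_thomas(
    params: ThomasParams,
    surface: IntensitySurface,
    window: ObservationWindow,
    seed=None,
    compensate: bool = False,
) -> np.ndarray:
    """Thomas realisation independently thinned by surface/max(surface).

    With ``compensate=True`` the pre-thinning intensity is inflated by the
    inverse mean retention so the surviving intensity is ≈ λ.
    """
    rng = as_rng(seed)
    if compensate:
        mean_ret = surface.integral(window) / (
            surface.max_value(window) * window.area
        )
        mean_ret = max(mean_ret, 1e-9)
        params = ThomasParams(
            params.sigma, params.rho, params.lambda_total / mean_ret
        )
    pts = simulate_thomas(params, window, rng)
    if len(pts) == 0:
        return pts
    vmax = surface.max_value(window)
    if vmax <= 0:
        return np.empty((0, 2), float)
    retention = surface.evaluate(pts[:, 0], pts[:, 1]) / vmax
    return pts[rng.uniform(0, 1, len(pts)) < retention]


# ---------------------------------------------------------------------------
# Minimal-contrast fitting
# ---------------------------------------------------------------------------


def _aggregation_mask(r: np.ndarray, g: np.ndarray, r_exclusion: float) -> np.ndarray:
    """Contiguous run of g > 1 containing the PCF maximum, beyond r_exclusion."""
    eligible = r > r_exclusion
    above = (g > 1.0) & eligible
    if not above.any():
        raise NoAggregationError("observed PCF never exceeds 1 beyond r_exclusion")
    peak = int(np.flatnonzero(eligible)[np.argmax(g[eligible])])
    if not above[peak]:  # peak at an excluded distance: use the first run
        peak = int(np.flatnonzero(above)[0])
    lo = peak
    while lo - 1 >= 0 and above[lo - 1]:
        lo -= 1
    hi = peak
    while hi + 1 < len(r) and above[hi + 1]:
        hi += 1
    mask = np.zeros(len(r), bool)
    mask[lo : hi + 1] = True
    return mask


def _contrast(
    obs_g: np.ndarray,
    obs_K: np.ndarray | None,
    model_g: np.ndarray,
    model_K: np.ndarray | None,
    basis: str,
) -> float:
    total = 0.0
    if "pcf" in basis:
        total += float(((obs_g - model_g) ** 2).sum())
    if "l" in basis:
        total += float(
            ((np.maximum(obs_K, 0) ** 0.25 - np.maximum(model_K, 0) ** 0.25) ** 2).sum()
        )
    return total


def fit_minimal_contrast(
    observed_g: SummaryCurve,
    observed_L: SummaryCurve | None = None,
    model_family: str = "TC",
    lambda_total: float = 1.0,
    fit_basis: str = "pcf+l",
    r_exclusion: float = 0.02,
    smoothing_span: int = 1,
) -> ThomasParams | DoubleThomasParams:
    """Fit a (double) Thomas process to observed summary curves.

    Minimises the summed squared discrepancy over the fitted basis
    ("pcf+l", "pcf" or "l") on the contiguous aggregated region of the
    distance grid (observed g > 1, r > r_exclusion).  λ is held at the
    observed overall intensity; the free parameters are (σ, ρ) for TC and
    (σ_small, σ_large, ρ_large, μ_large) for DTC, optimised on log scale by
    Nelder–Mead from several starting points.

    When the observed g was moving-average smoothed, pass the same
    ``smoothing_span`` so the model curve is smoothed identically before
    comparison — otherwise the peak flattening introduced by smoothing
    biases the fit.
    """
    if model_family not in ("TC", "DTC"):
        raise ValueError("model_family must be 'TC' or 'DTC'")
    if "l" in fit_basis and observed_L is None:
        raise ValueError(f"fit_basis {fit_basis!r} needs an observed L curve")
    if "pcf" not in fit_basis and "l" not in fit_basis:
        raise ValueError("fit_basis must mention 'pcf' and/or 'l'")
    from .summary import moving_average

    r = observed_g.r
    g = observed_g.values
    mask = _aggregation_mask(r, g, r_exclusion)
    r_fit, g_fit = r[mask], g[mask]
    K_fit = (
        np.pi * observed_L.values[mask] ** 2 if observed_L is not None else None
    )

    def model_g(pcf_func, p):
        return moving_average(pcf_func(p, r), smoothing_span)[mask]

    excess = max(float(g_fit.max()) - 1.0, 1e-3)
    r_peak = float(r_fit[np.argmax(g_fit)])
    sigma_starts = {max(r_peak, 0.02), 0.05, 0.1, 0.25, 0.5}

    if model_family == "TC":

        sigma_hi = 4 * float(r.max())  # beyond the grid σ is unidentifiable

        def objective(theta):
            sigma, rho = np.exp(theta)
            if not (1e-4 <= sigma <= sigma_hi and 1e-8 <= rho <= 1e8):
                return 1e12
            p = ThomasParams(sigma, rho, lambda_total)
            mk = thomas_K(p, r_fit) if K_fit is not None else None
            return _contrast(g_fit, K_fit, model_g(thomas_pcf, p), mk, fit_basis)

        best = None
        for s0 in sigma_starts:
            rho0 = 1.0 / (4 * math.pi * s0**2 * excess)
            res = minimize(
                objective,
                np.log([s0, rho0]),
                method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        sigma, rho = np.exp(best.x)
        return ThomasParams(float(sigma), float(rho), lambda_total)

    # DTC: initialise around a single-scale fit
    tc = fit_minimal_contrast(
        observed_g, observed_L, "TC", lambda_total, fit_basis, r_exclusion,
        smoothing_span,
    )

    sigma_hi = 4 * float(r.max())

    def objective4(theta):
        s_s, s_l, rho_l, mu_l = np.exp(theta)
        if not (
            1e-4 <= s_s <= sigma_hi
            and 1e-4 <= s_l <= sigma_hi
            and 1e-8 <= rho_l <= 1e8
            and 1e-6 <= mu_l <= 1e6
        ):
            return 1e12
        large = ThomasParams(s_l, rho_l, rho_l * mu_l)
        p = DoubleThomasParams(large, s_s, lambda_total / (rho_l * mu_l))
        mk = double_thomas_K(p, r_fit) if K_fit is not None else None
        return _contrast(g_fit, K_fit, model_g(double_thomas_pcf, p), mk, fit_basis)

    best = None
    for f_small, f_large in ((0.4, 2.0), (0.25, 4.0), (0.6, 1.5)):
        theta0 = np.log(
            [max(tc.sigma * f_small, 1e-3), tc.sigma * f_large, tc.rho, 3.0]
        )
        res = minimize(
            objective4,
            theta0,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    s_s, s_l, rho_l, mu_l = np.exp(best.x)
    large = ThomasParams(float(s_l), float(rho_l), float(rho_l * mu_l))
    return DoubleThomasParams(large, float(s_s), float(lambda_total / (rho_l * mu_l)))


# ---------------------------------------------------------------------------
# The model-fitting protocol
# ---------------------------------------------------------------------------


@dataclass
class CandidateFit:
    """One rung of the model ladder, with its envelope and p_d scores."""

    kind: str
    params: object | None
    gof_pcf: GofResult
    gof_nn: GofResult
    envelope: EnvelopeResult = field(repr=False, default=None)
    fit_basis: str | None = None
    extra: dict = field(default_factory=dict)

    @property
    def p_d_pcf(self) -> float:
        return self.gof_pcf.p_d

    @property
    def p_d_nn(self) -> float:
        return self.gof_nn.p_d

    @property
    def min_pd(self) -> float:
        return min(self.p_d_pcf, self.p_d_nn)


@dataclass
class FittedModel:
    """Outcome of the model ladder for one taxon pattern."""

    kind: str  # CSR | HP | TC | DTC | ITC | SEGREGATED
    params: object | None
    p_d_pcf: float
    p_d_nn: float
    candidates: dict[str, CandidateFit]
    fit_basis: str | None
    r_exclusion: float
    n_points: int

    @property
    def best_candidate(self) -> CandidateFit | None:
        return self.candidates.get(self.kind)


def _excursion_steps(exc: tuple[float, float, int], bandwidth: float) -> int:
    r0, r1, _ = exc
    return int(round((r1 - r0) / bandwidth)) + 1


def _long_excursions(env: EnvelopeResult, config: AnalysisConfig):
    return [
        e
        for e in env.excursions
        if _excursion_steps(e, config.bandwidth) > config.max_excursion_steps
    ]


def _rung(
    pattern: np.ndarray,
    window: ObservationWindow,
    simulator: Callable[[np.random.Generator], np.ndarray],
    config: AnalysisConfig,
    rng: np.random.Generator,
    obs_pcf: SummaryCurve,
    obs_nn: SummaryCurve,
    n_sims: int | None = None,
    gof_range: tuple[float, float] | None = None,
    with_nn: bool = True,
) -> tuple[EnvelopeResult, GofResult, GofResult | None]:
    """Simulate one model, envelope its PCF and score p_d on PCF and NN.

    ``gof_range`` restricts Diggle's test to the model's fitted distance
    range (cluster models are only asked to explain the aggregated part of
    the curve); the envelope always spans the whole grid.
    """
    n_sims = n_sims or config.n_sims
    rank = max(1, round(config.envelope_rank * (n_sims + 1) / 1000))
    grid = config.grid
    pcf_sims = np.empty((n_sims, len(obs_pcf.r)))
    nn_sims = np.empty((n_sims, len(obs_nn.r)))
    for i in range(n_sims):
        pts = simulator(rng)
        if len(pts) < 2:  # degenerate simulation: flat curves
            pcf_sims[i] = 1.0
            nn_sims[i] = 0.0
            continue
        pcf_sims[i] = estimate_pcf(pts, window, grid).values
        if with_nn:
            nn_sims[i] = estimate_nn(pts, window, grid).values
    obs = SummaryCurve(
        obs_pcf.kind, obs_pcf.r, obs_pcf.values.copy(), obs_pcf.n_points, obs_pcf.bandwidth
    )
    part = np.sort(pcf_sims, axis=0)
    lo, hi = part[rank - 1], part[n_sims - rank]
    from .nullmodels import _find_excursions

    exc = _find_excursions(obs.r, obs.values, lo, hi)
    obs.envelope_lo, obs.envelope_hi, obs.n_sims = lo, hi, n_sims
    env = EnvelopeResult(obs, lo, hi, n_sims, rank, exc, sim_values=pcf_sims)
    r_range = gof_range or (config.r_exclusion, config.r_max)
    gof_pcf = diggle_gof(obs_pcf, pcf_sims, r_range)
    gof_nn = diggle_gof(obs_nn, nn_sims, r_range) if with_nn else None
    return env, gof_pcf, gof_nn


def _acceptable(cand: CandidateFit, config: AnalysisConfig, pd_threshold: float) -> bool:
    return (
        not _long_excursions(cand.envelope, config)
        and cand.p_d_pcf > pd_threshold
        and cand.p_d_nn > pd_threshold
    )


def _second_scale_detected(cand: CandidateFit, config: AnalysisConfig) -> bool:
    """A second positive residual excursion wider than 2 grid steps."""
    env = cand.envelope
    model_g = env.sim_values.mean(axis=0)
    resid_above = env.observed.values > np.maximum(env.hi, model_g)
    runs = 0
    k = 0
    while k < len(resid_above):
        if resid_above[k]:
            j = k
            while j + 1 < len(resid_above) and resid_above[j + 1]:
                j += 1
            if j - k + 1 > 2:
                runs += 1
            k = j + 1
        else:
            k += 1
    return runs >= 1


def fit_protocol(
    pattern,
    window: ObservationWindow,
    config: AnalysisConfig | None = None,
    seed=None,
) -> FittedModel:
    """Run the full model ladder on one taxon pattern.

    Rungs, in order of increasing model complexity: CSR, heterogeneous
    Poisson (HP, moving-window background), Thomas cluster (TC), double
    Thomas (DTC) and inhomogeneous Thomas (ITC).  A pattern falling below
    the CSR envelope with no aggregation signal is labelled SEGREGATED.
    The first rung with no sustained envelope excursion and acceptable p_d
    on both the PCF and the nearest-neighbour function wins; if none is
    acceptable, the candidate with the largest worst-case p_d is reported.
    All candidate fits are retained for reporting.
    """
    config = config or AnalysisConfig()
    pts = np.asarray(pattern, float)
    n = len(pts)
    if n < config.min_n:
        raise InsufficientDataError(f"need at least {config.min_n} points, got {n}")
    rng = as_rng(seed)
    grid = config.grid
    lam = n / window.area
    obs_pcf = estimate_pcf(pts, window, grid)
    obs_nn = estimate_nn(pts, window, grid)
    obs_L = estimate_L(pts, window, grid)
    candidates: dict[str, CandidateFit] = {}

    def finish(kind: str) -> FittedModel:
        cand = candidates[kind] if kind in candidates else candidates["CSR"]
        return FittedModel(
            kind=kind,
            params=cand.params,
            p_d_pcf=cand.p_d_pcf,
            p_d_nn=cand.p_d_nn,
            candidates=candidates,
            fit_basis=cand.fit_basis,
            r_exclusion=config.r_exclusion,
            n_points=n,
        )

    # --- rung 1: CSR --------------------------------------------------
    env, gp, gn = _rung(
        pts, window, lambda r: simulate_csr(window, n=n, seed=r), config, rng,
        obs_pcf, obs_nn,
    )
    candidates["CSR"] = CandidateFit("CSR", None, gp, gn, env)
    long_exc = _long_excursions(env, config)
    if not long_exc and gp.p_d > config.csr_accept_pd and gn.p_d > config.csr_accept_pd:
        return finish("CSR")
    signs = {s for *_, s in long_exc} or env.excursion_signs()

    # --- segregation: below the envelope, never above -----------------
    if signs == {-1}:
        candidates["SEGREGATED"] = CandidateFit("SEGREGATED", None, gp, gn, env)
        return finish("SEGREGATED")

    # --- rung 2: heterogeneous Poisson --------------------------------
    R_list = [config.hp_fixed_R] if config.hp_fixed_R else list(config.R_grid)
    best_R, best_pd = R_list[0], -1.0
    if len(R_list) > 1:
        for R in R_list:
            surf = moving_window_intensity(pts, window, R)
            _, gp_r, _ = _rung(
                pts, window,
                lambda r, s=surf: simulate_heterogeneous_poisson(s, window, seed=r, n=n),
                config, rng, obs_pcf, obs_nn, n_sims=config.hp_search_sims,
                with_nn=False,
            )
            if gp_r.p_d > best_pd:
                best_R, best_pd = R, gp_r.p_d
    hp_surface = moving_window_intensity(pts, window, best_R)
    env, gp, gn = _rung(
        pts, window,
        lambda r: simulate_heterogeneous_poisson(hp_surface, window, seed=r, n=n),
        config, rng, obs_pcf, obs_nn,
    )
    candidates["HP"] = CandidateFit(
        "HP", hp_surface, gp, gn, env, extra={"R": best_R}
    )
    if _acceptable(candidates["HP"], config, config.model_accept_pd):
        return finish("HP")

    # --- rung 3: Thomas cluster, with fit-basis fallback ---------------
    # cluster rungs are scored over the model's fitted range: the
    # contiguous aggregated region of the observed PCF
    try:
        agg = _aggregation_mask(obs_pcf.r, obs_pcf.values, config.r_exclusion)
        cluster_range = (config.r_exclusion, float(obs_pcf.r[agg][-1]))
    except NoAggregationError:
        cluster_range = (config.r_exclusion, config.r_max)
    tc_cand = None
    try:
        for basis in ("pcf+l", "pcf", "l"):
            params = fit_minimal_contrast(
                obs_pcf, obs_L, "TC", lam, basis, config.r_exclusion,
                config.smoothing_span,
            )
            try:
                env, gp, gn = _rung(
                    pts, window,
                    lambda r, p=params: simulate_thomas(p, window, seed=r),
                    config, rng, obs_pcf, obs_nn, gof_range=cluster_range,
                )
            except ValueError:  # unsimulatable degenerate fit
                continue
            cand = CandidateFit("TC", params, gp, gn, env, fit_basis=basis)
            if tc_cand is None or cand.min_pd > tc_cand.min_pd:
                tc_cand = cand
            if basis == "pcf+l" and gp.p_d >= config.refit_pd:
                break
            if basis == "pcf" and gn.p_d >= config.refit_pd:
                break
        if tc_cand is not None:
            candidates["TC"] = tc_cand
            if _acceptable(tc_cand, config, config.model_accept_pd):
                return finish("TC")
    except NoAggregationError:
        tc_cand = None

    # --- rung 4: inhomogeneous Thomas (TC on the HP background) --------
    # independent thinning factorises the product density, so the cluster
    # component is fitted to the observed g divided by the background's
    # g (the mean PCF of the heterogeneous-Poisson simulations)
    g_bg = np.maximum(candidates["HP"].envelope.sim_values.mean(axis=0), 1e-6)
    corrected = SummaryCurve(
        "pcf", obs_pcf.r, obs_pcf.values / g_bg, n, obs_pcf.bandwidth
    )
    try:
        itc_params = fit_minimal_contrast(
            corrected, None, "TC", lam, "pcf", config.r_exclusion,
            config.smoothing_span,
        )
    except NoAggregationError:
        itc_params = tc_cand.params if tc_cand is not None else None
    if itc_params is not None:
        try:
            env, gp, gn = _rung(
                pts, window,
                lambda r: simulate_inhom_thomas(
                    itc_params, hp_surface, window, seed=r, compensate=True
                ),
                config, rng, obs_pcf, obs_nn, gof_range=cluster_range,
            )
        except ValueError:
            env = None
        if env is not None:
            candidates["ITC"] = CandidateFit(
                "ITC", itc_params, gp, gn, env,
                fit_basis="pcf", extra={"R": best_R},
            )
            if _acceptable(candidates["ITC"], config, config.model_accept_pd):
                return finish("ITC")

    # --- rung 5: double Thomas, when a second cluster scale shows ------
    if (
        tc_cand is not None
        and tc_cand.min_pd < config.dtc_trigger_pd
        and _second_scale_detected(tc_cand, config)
    ):
        try:
            dparams = fit_minimal_contrast(
                obs_pcf, obs_L, "DTC", lam, tc_cand.fit_basis or "pcf+l",
                config.r_exclusion, config.smoothing_span,
            )
            env, gp, gn = _rung(
                pts, window,
                lambda r, p=dparams: simulate_double_thomas(p, window, seed=r),
                config, rng, obs_pcf, obs_nn, gof_range=cluster_range,
            )
            candidates["DTC"] = CandidateFit(
                "DTC", dparams, gp, gn, env, fit_basis=tc_cand.fit_basis
            )
            if _acceptable(candidates["DTC"], config, config.model_accept_pd):
                return finish("DTC")
        except (NoAggregationError, ValueError):
            pass

    # --- nothing acceptable: report the least-bad candidate ------------
    scored = {k: c for k, c in candidates.items() if k != "SEGREGATED"}
    best_kind = max(scored, key=lambda k: scored[k].min_pd)
    return finish(best_kind)
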