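"""Differential-erosion bias detection via competing intensity models.

Modern erosion can thin a fossil surface unevenly — typically along strike
(x), along dip (y), or radially from the most exposed point (e.g. nearest
the sea).  Each candidate is an inhomogeneous Poisson process with
log-linear intensity λ(x, y) = exp(a + b·z) in one covariate z ∈
{1, x, y, distance-to-anchor}, fitted by maximising the Poisson
point-process log-likelihood

    ℓ(a, b) = Σ_points log λ − ∫_W λ ,

and compared by AIC.  The log link guarantees positivity and makes the
homogeneous model the b = 0 special case.  The intercept is profiled out
analytically (the MLE satisfies ∫_W λ̂ = n exactly), leaving a 1-D
optimisation in b.  A heterogeneous model is adopted when it beats the
homogeneous one by more than 2 AIC units; the winning surface can then
serve as the background intensity for the null models downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import minimize_scalar

from .errors import InsufficientDataError
from .geometry import ObservationWindow
from .nullmodels import CallableIntensity, IntensitySurface

MODEL_KINDS = ("homogeneous", "gradient_x", "gradient_y", "radial_from_point")


@dataclass(frozen=True)
class ErosionModelFit:
    """One fitted erosion-intensity model with its AIC score."""

    model_kind: str
    params: dict  # {"a": intercept, "b": slope, "anchor": (x, y) | None}
    log_likelihood: float
    aic: float
    n_params: int

    @property
    def intercept(self) -> float:
        return self.params["a"]

    @property
    def slope(self) -> float:
        return self.params.get("b", 0.0)


def _covariate(kind: str, anchor):
    if kind == "gradient_x":
        return lambda x, y: np.asarray(x, float)
    if kind == "gradient_y":
        return lambda x, y: np.asarray(y, float)
    if kind == "radial_from_point":
        ax, ay = anchor
        return lambda x, y: np.hypot(np.asarray(x, float) - ax, np.asarray(y, float) - ay)
    raise ValueError(kind)


class _ExpIntegral:
    """∫_W exp(b·z) dx dy as a function of b, by tensor Gauss–Legendre.

    Analytic along x or y on rectangular windows; numeric (128² nodes,
    masked by the window polygon) for the radial covariate or non-
    rectangular windows.  The integrand is smooth, so the quadrature error
    is far below the optimizer tolerance.
    """

    def __init__(self, kind: str, window: ObservationWindow, anchor, order: int = 128):
        self.kind = kind
        self.window = window
        xmin, ymin, xmax, ymax = window.bounds
        self._analytic = window.is_rectangle and kind in ("gradient_x", "gradient_y")
        if self._analytic:
            if kind == "gradient_x":
                self._lo, self._hi, self._span = xmin, xmax, ymax - ymin
            else:
                self._lo, self._hi, self._span = ymin, ymax, xmax - xmin
        else:
            nodes, weights = leggauss(order)
            xs = 0.5 * (xmax - xmin) * (nodes + 1) + xmin
            ys = 0.5 * (ymax - ymin) * (nodes + 1) + ymin
            gx, gy = np.meshgrid(xs, ys, indexing="ij")
            wx, wy = np.meshgrid(weights, weights, indexing="ij")
            w2 = wx * wy * 0.25 * (xmax - xmin) * (ymax - ymin)
            gx, gy, w2 = gx.ravel(), gy.ravel(), w2.ravel()
            if not window.is_rectangle:
                inside = window.contains(gx, gy)
                gx, gy, w2 = gx[inside], gy[inside], w2[inside]
            self._z = _covariate(kind, anchor)(gx, gy)
            self._w = w2

    def log(self, b: float) -> float:
        """log ∫_W exp(b·z), computed in log space to avoid overflow."""
        if self._analytic:
            span_z = self._hi - self._lo
            if abs(b) < 1e-12:
                return math.log(span_z * self._span)
            if b > 0:
                return (
                    math.log(self._span) + b * self._hi
                    + math.log(-math.expm1(-b * span_z)) - math.log(b)
                )
            return (
                math.log(self._span) + b * self._lo
                + math.log(-math.expm1(b * span_z)) - math.log(-b)
            )
        zmax = float(self._z.max()) if b >= 0 else float(self._z.min())
        return b * zmax + math.log(float(np.sum(self._w * np.exp(b * (self._z - zmax)))))

    def __call__(self, b: float) -> float:
        return math.exp(self.log(b))


def _fit_one(
    kind: str,
    points: np.ndarray,
    window: ObservationWindow,
    anchor,
) -> ErosionModelFit:
    n = len(points)
    area = window.area
    if kind == "homogeneous":
        a = math.log(n / area)
        ll = n * a - n
        return ErosionModelFit(kind, {"a": a, "anchor": None}, ll, 2 * 1 - 2 * ll, 1)
    z = _covariate(kind, anchor)(points[:, 0], points[:, 1])
    xmin, ymin, xmax, ymax = window.bounds
    px, py = np.meshgrid(
        np.linspace(xmin, xmax, 5), np.linspace(ymin, ymax, 5), indexing="ij"
    )
    probe = _covariate(kind, anchor)(px.ravel(), py.ravel())
    if float(probe.max() - probe.min()) < 1e-12:
        raise ValueError(f"degenerate window extent for covariate {kind}")
    integral = _ExpIntegral(kind, window, anchor)
    z_sum = float(z.sum())

    def neg_profile_ll(b: float) -> float:
        # profile intercept: exp(a) = n / ∫ exp(bz)
        return -(n * (math.log(n) - integral.log(b)) + b * z_sum - n)

    res = minimize_scalar(neg_profile_ll, bounds=(-50.0, 50.0), method="bounded",
                          options={"xatol": 1e-10})
    b = float(res.x)
    a = math.log(n) - integral.log(b)
    ll = -float(res.fun)
    params = {"a": a, "b": b, "anchor": tuple(anchor) if kind == "radial_from_point" else None}
    return ErosionModelFit(kind, params, ll, 2 * 2 - 2 * ll, 2)


def fit_erosion_models(
    pattern,
    window: ObservationWindow,
    anchor: tuple[float, float] | None = None,
) -> list[ErosionModelFit]:
    """Fit the competing erosion-intensity models, sorted by AIC (best first).

    ``anchor`` is the point from which erosion is considered most likely to
    radiate (e.g. the corner nearest the sea); when omitted the radial
    model is skipped.  Degenerate covariates (zero window extent) are
    skipped with a notice.
    """
    points = np.asarray(pattern, float)
    if len(points) < 10:
        raise InsufficientDataError("erosion model fitting needs at least 10 points")
    kinds = ["homogeneous", "gradient_x", "gradient_y"]
    if anchor is not None:
        kinds.append("radial_from_point")
    fits = []
    for kind in kinds:
        try:
            fits.append(_fit_one(kind, points, window, anchor))
        except ValueError as e:
            import warnings

            warnings.warn(f"skipping erosion model {kind}: {e}", stacklevel=2)
    return sorted(fits, key=lambda f: f.aic)


def select_erosion_model(
    fits: list[ErosionModelFit], aic_margin: float = 2.0
) -> tuple[ErosionModelFit, bool]:
    """Pick the AIC-best model; adopt heterogeneity only with > 2 AIC support.

    Returns ``(fit, adopted)`` where ``adopted`` is False when the
    homogeneous model is within ``aic_margin`` of the best heterogeneous
    one (no significant erosion signal).
    """
    best = fits[0]
    homo = next(f for f in fits if f.model_kind == "homogeneous")
    if best.model_kind == "homogeneous" or homo.aic - best.aic <= aic_margin:
        return homo, False
    return best, True


def apply_bias_surface(fit: ErosionModelFit) -> IntensitySurface:
    """Turn a fitted erosion model into an IntensitySurface for the nulls."""
    a = fit.intercept
    if fit.model_kind == "homogeneous":
        from .nullmodels import ConstantIntensity

        return ConstantIntensity(math.exp(a))
    b = fit.slope
    cov = _covariate(fit.model_kind, fit.params.get("anchor"))
    return CallableIntensity(
        lambda x, y: np.exp(a + b * cov(x, y)), kind=f"erosion_{fit.model_kind}"
    )
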