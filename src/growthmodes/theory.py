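"""Closed-form small-noise predictions for regression and binning.

For the class of models where birth controls division through
``f(l_b) = 2 l_b**(1-alpha)`` and noise is small, every "natural plot"
of per-cycle observables is, to first order, a linear combination of
three independent zero-mean Gaussian components:

* ``x``   — the stationary log birth-size fluctuation, variance
  ``sigma_n**2 / (alpha (2 - alpha))`` (exponential growth) or its
  linear-growth analogue ``sigma_bd**2 / (4 alpha (2 - alpha))``;
* ``xi``  — the per-cycle rate fluctuation, variance ``cv_lambda**2``;
* ``zeta``— the division-timing noise.

Each supported plot axis is expressed in these components, and slope,
intercept and Pearson correlation follow from the implied means,
variances and covariance (``m = rho * sigma_y / sigma_x``,
``c = <y> - m <x>``).  This single code path reproduces all of the
printed special cases, e.g. a slope of exactly 1 with zero intercept
for normalized generation time vs log size ratio under exponential
growth (any alpha, any noise), and a slope (3/2) ln 2 ~ 1.0397 with
intercept ~ -0.0275 for the same plot when growth is truly linear.

All formulas here are first-order in the noise; they are meant for
sigma, CV <~ 0.2 (the data-like regime is 0.15) and are validated
against simulation in the test suite, not extended beyond first order.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .params import LN2, GrowthMode, ModelParams, NoiseKind

__all__ = [
    "PlotAxes",
    "RegressionResult",
    "DerivedMoments",
    "stationary_moments",
    "predicted_regression",
    "predicted_binned_trend",
    "binned_trend_coefficients",
    "growth_rate_age_curve",
]


class PlotAxes(str, enum.Enum):
    """The four y-vs-x axis choices the framework covers.

    ``logratio`` is ln(Ld/Lb); ``lamTd`` is <lambda> Td; ``sizediff`` is
    (Ld - Lb)/<Lb>; ``lamlinTd`` is <lambda_lin> Td.  Names read
    y_vs_x.
    """

    LOGRATIO_VS_LAMTD = "logratio_vs_lamTd"
    LAMTD_VS_LOGRATIO = "lamTd_vs_logratio"
    SIZEDIFF_VS_LAMLINTD = "sizediff_vs_lamlinTd"
    LAMLINTD_VS_SIZEDIFF = "lamlinTd_vs_sizediff"


@dataclass(frozen=True)
class RegressionResult:
    """Slope, intercept and Pearson correlation of a designated plot."""

    slope: float
    intercept: float
    correlation: float

    def __post_init__(self) -> None:
        if not -1.0000001 <= self.correlation <= 1.0000001:
            raise ValueError("correlation outside [-1, 1]")


@dataclass(frozen=True)
class DerivedMoments:
    """Stationary variances of the per-cycle observables.

    ``var_x`` — log birth-size fluctuation (dimensionless);
    ``var_Td`` — generation time (min^2);
    ``var_logratio`` — ln(Ld/Lb);
    ``var_lb`` — normalized birth length;
    ``var_sizediff`` — normalized added length ld - lb.
    """

    var_x: float
    var_Td: float
    var_logratio: float
    var_lb: float
    var_sizediff: float


# ----------------------------------------------------------------------
# first-order axis decompositions
# ----------------------------------------------------------------------

def _components(params: ModelParams) -> dict[str, float]:
    """Variances of the independent components (x, xi, zeta-equivalent)."""
    a = params.alpha
    if a == 0.0 or a >= 2.0:
        raise ValueError(
            "stationary fluctuations require 0 < alpha < 2 (variance diverges at the "
            "timer limit alpha = 0)"
        )
    if params.growth_mode is GrowthMode.LINEAR:
        # for linear growth a time-additive noise zeta/<lam_lin> shifts the
        # added length by ~zeta, so the size-additive equivalent SD is sigma_n
        sbd = params.sigma_bd if params.noise_kind is NoiseKind.SIZE_ADDITIVE \
            else params.sigma_n
        var_delta = sbd**2 / (4.0 * a * (2.0 - a))
        return {"var_x": var_delta, "var_xi": params.cv_lambda**2, "var_z": sbd**2}
    sn = params.sigma_n_effective()
    var_x = sn**2 / (a * (2.0 - a))
    return {"var_x": var_x, "var_xi": params.cv_lambda**2, "var_z": sn**2}


def _axis_decomposition(axis: str, params: ModelParams) -> tuple[float, float, float, float]:
    """(mean, coef_x, coef_xi, coef_zeta) of an axis variable, first order.

    The zeta unit is the time-additive noise (exponential truth) or the
    size-additive noise (linear truth); coefficients below are written
    in that unit.
    """
    a = params.alpha
    truth = params.growth_mode
    if truth is GrowthMode.EXPONENTIAL:
        # zeta ~ N(0, sigma_n); size-additive noise = 2 zeta to first order
        if axis == "logratio":
            return LN2, -a, 0.0, 1.0
        if axis == "lamTd":
            return LN2, -a, -LN2, 1.0
        if axis == "sizediff":
            return 1.0, 1.0 - 2.0 * a, 0.0, 2.0
        if axis == "lamlinTd":
            return 1.0, -a / LN2, -1.0, 1.0 / LN2
    elif truth is GrowthMode.LINEAR:
        # zeta ~ N(0, sigma_bd), size additive; x here is delta = l_b - 1
        if axis == "sizediff":
            return 1.0, 1.0 - 2.0 * a, 0.0, 1.0
        if axis == "lamlinTd":
            return 1.0, 1.0 - 2.0 * a, -1.0, 1.0
        if axis == "logratio":
            return LN2, -a, 0.0, 0.5
        if axis == "lamTd":
            return LN2, LN2 * (1.0 - 2.0 * a), -LN2, LN2
    raise ValueError(f"axis {axis!r} has no first-order form for growth mode {truth}")


def stationary_moments(params: ModelParams) -> DerivedMoments:
    """Evaluate the stationary variances for the given model.

    Under exponential growth: ``var_x = sigma_n^2/(alpha(2-alpha))``,
    ``var_logratio = 2 sigma_n^2/(2-alpha)``, and ``var_Td`` combines
    rate and timing noise.  Under linear growth the analogous
    expressions hold with the size-additive noise and the normalized
    birth-length fluctuation.  Raises at the ``alpha = 0`` pole.
    """
    comp = _components(params)
    if params.growth_mode is GrowthMode.LINEAR:
        scale_t = 1.0 / params.mean_elongation_speed_norm
        t_axis = "lamlinTd"
    else:
        scale_t = 1.0 / params.mean_growth_rate
        t_axis = "lamTd"

    def var_of(axis: str) -> float:
        _, cx, cxi, cz = _axis_decomposition(axis, params)
        return cx**2 * comp["var_x"] + cxi**2 * comp["var_xi"] + cz**2 * comp["var_z"]

    return DerivedMoments(
        var_x=comp["var_x"],
        var_Td=var_of(t_axis) * scale_t**2,
        var_logratio=var_of("logratio"),
        var_lb=comp["var_x"],
        var_sizediff=var_of("sizediff"),
    )


def predicted_regression(plot: PlotAxes | str, params: ModelParams) -> RegressionResult:
    """Closed-form OLS slope/intercept/correlation for a designated plot.

    The plot axes fix what is regressed on what; ``params.growth_mode``
    fixes the true generative growth law.  Normalizations follow
    ``<lambda> = ln 2 / <Td>`` and ``<lambda_lin> = <lambda> / ln 2``.
    """
    plot = PlotAxes(plot)
    y_axis, x_axis = plot.value.split("_vs_")
    comp = _components(params)
    my, cyx, cyxi, cyz = _axis_decomposition(y_axis, params)
    mx, cxx, cxxi, cxz = _axis_decomposition(x_axis, params)
    var_y = cyx**2 * comp["var_x"] + cyxi**2 * comp["var_xi"] + cyz**2 * comp["var_z"]
    var_x = cxx**2 * comp["var_x"] + cxxi**2 * comp["var_xi"] + cxz**2 * comp["var_z"]
    cov = (
        cyx * cxx * comp["var_x"]
        + cyxi * cxxi * comp["var_xi"]
        + cyz * cxz * comp["var_z"]
    )
    slope = cov / var_x
    intercept = my - slope * mx
    correlation = cov / math.sqrt(var_x * var_y)
    return RegressionResult(slope=slope, intercept=intercept, correlation=correlation)


# ----------------------------------------------------------------------
# conditional expectations (binned-trend curves)
# ----------------------------------------------------------------------

def binned_trend_coefficients(params: ModelParams) -> tuple[float, float]:
    """(linear, quadratic) coefficients of E[ln(Ld/Lb) | <lambda>Td].

    The conditional expectation for exponential growth expands as
    ``(1 + A) s - (A/ln 2) s**2`` in ``s = <lambda> Td``, with
    ``A = 1 / (1 + (2/(2-alpha)) sigma_n^2 / (CV_lambda^2 ln^2 2))``.
    At the adder with sigma_n = CV_lambda = 0.15 this is
    ``1.26 s - 0.38 s**2`` to two decimals.
    """
    if params.growth_mode is not GrowthMode.EXPONENTIAL:
        raise ValueError("binned-trend curve derived for exponential growth only")
    sn = params.sigma_n_effective()
    cv = params.cv_lambda
    if cv == 0.0:
        return 1.0, 0.0
    b = (2.0 / (2.0 - params.alpha)) * sn**2 / (cv**2 * LN2**2)
    a_coef = 1.0 / (1.0 + b)
    return 1.0 + a_coef, -a_coef / LN2


def predicted_binned_trend(
    plot: PlotAxes | str, params: ModelParams, x_values: Sequence[float]
) -> np.ndarray:
    """Theoretical binned-data curve E[y | x] at the given x values.

    Derived for exponential growth: the log-size-ratio vs normalized
    generation time plot follows the quadratic curve of
    :func:`binned_trend_coefficients`; with the axes interchanged the
    conditional expectation is exactly the identity.
    """
    plot = PlotAxes(plot)
    x = np.asarray(x_values, dtype=float)
    if plot is PlotAxes.LAMTD_VS_LOGRATIO:
        if params.growth_mode is not GrowthMode.EXPONENTIAL:
            raise ValueError("identity conditional expectation derived for exponential growth")
        return x.copy()
    if plot is PlotAxes.LOGRATIO_VS_LAMTD:
        c1, c2 = binned_trend_coefficients(params)
        return c1 * x + c2 * x**2
    raise ValueError(f"no derived conditional expectation for plot {plot.value!r}")


# ----------------------------------------------------------------------
# growth-rate vs age reference curves
# ----------------------------------------------------------------------

def growth_rate_age_curve(
    mode: GrowthMode | str, params: ModelParams, ages: Sequence[float]
) -> np.ndarray:
    """Reference growth-rate-vs-age curve lambda(age), in 1/min.

    Exponential growth is flat at the mean rate; linear growth decays as
    ``lambda(0) / (1 + age)`` with ``lambda(0) = <lambda>/ln 2`` so the
    cell doubles over the cycle; super-exponential growth is flat up to
    the crossover age and rises as ``lambda_0 + k (t - t_c)**2``
    afterwards, with the cycle duration taken at its deterministic
    adder value.
    """
    mode = GrowthMode(mode)
    a = np.asarray(ages, dtype=float)
    if np.any(a < 0.0) or np.any(a > 1.0):
        raise ValueError("ages must lie in [0, 1]")
    lam = params.mean_growth_rate
    if mode is GrowthMode.EXPONENTIAL:
        return np.full_like(a, lam)
    if mode is GrowthMode.LINEAR:
        return (lam / LN2) / (1.0 + a)
    k = params.superexp_k
    f = params.superexp_tc_frac
    # deterministic cycle duration: lam*T + k(1-f)^3 T^3/3 = ln 2
    from .simulate import _solve_division_time

    td = _solve_division_time(lam, k * (1.0 - f) ** 3 / 3.0, LN2)
    t = a * td
    return lam + k * np.clip(t - f * td, 0.0, None) ** 2
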