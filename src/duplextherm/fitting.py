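"""Thermodynamic parameter recovery from UV melting curves.

Two independent routes, consolidated the way melting studies report them:

1. **Direct nonlinear fitting** of each curve to the two-state transition
   model with linear duplex and single-strand baselines — six parameters:
   (ΔH°, Tm, b_ds, m_ds, b_ss, m_ss). The fit parameterizes the transition
   by (ΔH°, Tm) and derives ΔS° from the closed-form melting-temperature
   relation at the curve's strand concentration, which decorrelates the
   transition parameters compared with fitting (ΔH°, ΔS°) directly.

2. **The van't Hoff concentration plot**: ordinary least squares of Tm⁻¹ on
   log₁₀(Ct/4) across a strand-concentration series,

       Tm⁻¹ = (ΔS°/1000 + R·ln(Ct/4)/1000) / ΔH°
            = intercept + [2.303·R/ΔH°]·log₁₀(Ct/4)

   so ΔH° = 2.303·R/slope (R in kcal units) and ΔS° = 1000·intercept·ΔH°.

Agreement of the two routes (the default criterion: |ΔH°| within 15%) is
the standard evidence that a transition is genuinely two-state; the
consolidated parameters are the unweighted mean of the two routes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .constants import LN10, R_CAL, R_KCAL, celsius_to_kelvin
from .core import ThermoParams
from .simulate import MeltingCurve

__all__ = [
    "TwoStateFitResult",
    "VantHoffResult",
    "ConsolidatedParams",
    "NoTransitionError",
    "fit_two_state",
    "tm_from_derivative",
    "vant_hoff_regression",
    "consolidate_parameters",
]

#: Fraction of the temperature range used for initial baseline fits.
_BASELINE_FRACTION = 0.15

#: Default |ΔH°| agreement threshold for the two-state flag.
TWO_STATE_DH_TOLERANCE = 0.15


class NoTransitionError(ValueError):
    """The curve shows no detectable melting transition."""


@dataclass(frozen=True)
class TwoStateFitResult:
    """Result of fitting one melting curve to the two-state model."""

    params: ThermoParams
    b_ds: float
    m_ds: float
    b_ss: float
    m_ss: float
    Tm: float  # K, at this curve's Ct
    Ct: float  # M, total strand concentration
    sse: float
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class VantHoffResult:
    """Tm⁻¹ vs log₁₀(Ct/4) regression and the parameters it implies."""

    params: ThermoParams
    slope: float  # K⁻¹ per log10 unit
    intercept: float  # K⁻¹
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class ConsolidatedParams:
    """Average of the curve-fit and van't Hoff routes, with agreement flag."""

    params: ThermoParams
    curve_fit_params: ThermoParams
    vant_hoff_params: ThermoParams
    two_state_flag: bool
    dh_discrepancy: float  # |ΔH°_fit − ΔH°_vH| / |mean ΔH°|


def _dS_from_dh_tm(dH: float, Tm: float, Ct: float) -> float:
    """ΔS° (cal units) implied by ΔH°, Tm and Ct via the closed form."""
    return 1000.0 * dH / Tm - R_CAL * math.log(Ct / 4.0)


def _model_absorbance(
    theta: np.ndarray, t_celsius: np.ndarray, Ct: float
) -> np.ndarray:
    dH, Tm, b_ds, m_ds, b_ss, m_ss = theta
    dS = _dS_from_dh_tm(dH, Tm, Ct)
    t_kelvin = t_celsius + 273.15
    dg = dH - t_kelvin * dS / 1000.0
    k = np.exp(-dg / (R_KCAL * t_kelvin))
    a = k * Ct
    f = a / (a + 1.0 + np.sqrt(2.0 * a + 1.0))
    return f * (b_ds + m_ds * t_celsius) + (1.0 - f) * (b_ss + m_ss * t_celsius)


def _robust_noise_sd(absorbance: np.ndarray) -> float:
    """Noise scale from first differences, immune to the transition shape."""
    diffs = np.diff(absorbance)
    mad = np.median(np.abs(diffs - np.median(diffs)))
    return 1.4826 * mad / math.sqrt(2.0)


def tm_from_derivative(curve: MeltingCurve) -> float:
    """Transition temperature (K) as the maximum of the smoothed dA/dT.

    The derivative is smoothed with a centered 5-point moving average
    before locating the maximum; ties break toward the lowest temperature.
    Model-free, so it also serves long duplexes whose transitions are not
    analyzed thermodynamically.

    .. note::
       For a bimolecular transition the steepest point of the curve lies
       slightly above the thermodynamic Tm (where f = 1/2): the duplex
       fraction at maximum slope is ≈ 0.42, displacing the peak upward by
       roughly R·Tm²/|ΔH°| ≈ 1 K for a typical 13-mer. This estimator is
       therefore an initializer and a condition-comparison statistic, not
       a substitute for the closed-form Tm of a fitted curve.

    Raises :class:`NoTransitionError` when the derivative peak has no
    prominence over the baseline derivative level or sits on the grid
    boundary (a flat or baseline-only curve).
    """
    t = curve.temperatures
    dadt = np.gradient(curve.absorbance, t)
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(dadt, kernel, mode="same")
    # exclude the 2-point convolution edge effects from the search
    interior = smooth[2:-2]
    idx = 2 + int(np.argmax(interior))
    peak = float(smooth[idx])
    level = float(np.median(interior))
    spread = 1.4826 * float(np.median(np.abs(interior - level)))
    prominence_floor = max(3.0 * spread, 1e-9 * max(1.0, abs(level)))
    if peak - level <= prominence_floor or idx <= 2 or idx >= t.size - 3:
        raise NoTransitionError("no interior maximum in dA/dT: no transition detected")
    return celsius_to_kelvin(float(t[idx]))


def _initial_guess(curve: MeltingCurve) -> np.ndarray:
    t, a = curve.temperatures, curve.absorbance
    n_edge = max(2, int(round(_BASELINE_FRACTION * t.size)))
    m_ds, b_ds = np.polyfit(t[:n_edge], a[:n_edge], 1)
    m_ss, b_ss = np.polyfit(t[-n_edge:], a[-n_edge:], 1)
    try:
        tm0 = tm_from_derivative(curve)
    except NoTransitionError:
        tm0 = celsius_to_kelvin(float(t[t.size // 2]))
    return np.array([-80.0, tm0, b_ds, m_ds, b_ss, m_ss])


def fit_two_state(
    curve: MeltingCurve,
    max_iter: int = 500,
    ftol: float = 1e-10,
) -> TwoStateFitResult:
    """Nonlinear least-squares fit of the two-state model to one curve.

    Parameters are initialized from the derivative Tm, ΔH°₀ = −80
    kcal·mol⁻¹, and straight-line fits to the lowest and highest 15% of the
    temperature range. Non-convergence is reported through
    ``converged=False``, never raised, so batch pipelines continue.

    Raises
    ------
    NoTransitionError
        If the absorbance range does not exceed 3× a robust noise estimate
        (no transition to fit).
    """
    t, a = curve.temperatures, curve.absorbance
    noise = _robust_noise_sd(a)
    span = float(a.max() - a.min())
    if span <= 3.0 * noise or span == 0.0:
        raise NoTransitionError(
            f"absorbance range {span:.3g} does not exceed 3x noise estimate {noise:.3g}"
        )
    theta0 = _initial_guess(curve)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _model_absorbance(theta, t, curve.Ct) - a

    lower = [-400.0, 250.0, -np.inf, -np.inf, -np.inf, -np.inf]
    upper = [-1.0, 400.0, np.inf, np.inf, np.inf, np.inf]
    theta0[0] = np.clip(theta0[0], lower[0], upper[0])
    theta0[1] = np.clip(theta0[1], lower[1] + 1.0, upper[1] - 1.0)
    result = optimize.least_squares(
        residuals,
        theta0,
        bounds=(lower, upper),
        ftol=ftol,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=max_iter * len(theta0),
        x_scale=[10.0, 1.0, 0.01, 1e-4, 0.01, 1e-4],
    )
    dH, tm, b_ds, m_ds, b_ss, m_ss = (float(v) for v in result.x)
    dS = _dS_from_dh_tm(dH, tm, curve.Ct)
    return TwoStateFitResult(
        params=ThermoParams(dH=dH, dS=dS),
        b_ds=b_ds,
        m_ds=m_ds,
        b_ss=b_ss,
        m_ss=m_ss,
        Tm=tm,
        Ct=curve.Ct,
        sse=float(2.0 * result.cost),
        converged=bool(result.success),
        n_iter=int(result.nfev),
    )


def vant_hoff_regression(points: list[tuple[float, float]]) -> VantHoffResult:
    """OLS of Tm⁻¹ on log₁₀(Ct/4) over a strand-concentration series.

    ``points`` are (Ct in M, Tm in K) pairs; at least three distinct Ct
    values are required. For a duplex that melts (ΔH° < 0, Tm rising with
    Ct) the slope is negative; a non-negative slope implies ΔH° ≥ 0 and is
    rejected — the data are not a two-state melting concentration series.
    """
    if len(points) < 3:
        raise ValueError(f"van't Hoff regression needs >= 3 points, got {len(points)}")
    cts = np.array([p[0] for p in points], dtype=float)
    tms = np.array([p[1] for p in points], dtype=float)
    if np.unique(cts).size < 3:
        raise ValueError("van't Hoff regression needs >= 3 distinct Ct values")
    if np.any(cts <= 0) or np.any(tms <= 0):
        raise ValueError("Ct and Tm must be positive")
    x = np.log10(cts / 4.0)
    y = 1.0 / tms
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(
            f"non-negative van't Hoff slope {fit.slope:.3g} implies dH >= 0; "
            "not a two-state melting series"
        )
    dH = float(LN10 * R_KCAL / fit.slope)
    dS = float(1000.0 * fit.intercept * dH)
    return VantHoffResult(
        params=ThermoParams(dH=dH, dS=dS),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=len(points),
    )


def vant_hoff_from_fits(fits: list[TwoStateFitResult]) -> VantHoffResult:
    """Convenience: run the Tm⁻¹ plot on the (Ct, Tm) of converged fits."""
    pts = [(f.Ct, f.Tm) for f in fits if f.converged]
    return vant_hoff_regression(pts)


def consolidate_parameters(
    fits: list[TwoStateFitResult],
    vh: VantHoffResult,
    dh_tolerance: float = TWO_STATE_DH_TOLERANCE,
) -> ConsolidatedParams:
    """Average the curve-fit and van't Hoff routes.

    The curve-fit side is the mean (ΔH°, ΔS°) over converged fits only;
    the final parameters are the unweighted mean of that and the van't Hoff
    parameters, with ΔG°37 recomputed from the averaged ΔH° and ΔS°. The
    ``two_state_flag`` is set when the two |ΔH°| values agree within
    ``dh_tolerance`` (relative to their mean).
    """
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged fits to consolidate")
    fit_dh = float(np.mean([f.params.dH for f in converged]))
    fit_ds = float(np.mean([f.params.dS for f in converged]))
    fit_params = ThermoParams(dH=fit_dh, dS=fit_ds)
    mean_params = ThermoParams(
        dH=(fit_params.dH + vh.params.dH) / 2.0,
        dS=(fit_params.dS + vh.params.dS) / 2.0,
    )
    denom = abs(mean_params.dH)
    discrepancy = abs(fit_params.dH - vh.params.dH) / denom if denom else math.inf
    return ConsolidatedParams(
        params=mean_params,
        curve_fit_params=fit_params,
        vant_hoff_params=vh.params,
        two_state_flag=bool(discrepancy <= dh_tolerance),
        dh_discrepancy=discrepancy,
    )
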