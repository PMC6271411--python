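"""Salt-dependence analysis and counterion uptake.

Duplex formation takes up cations: raising the salt concentration
stabilizes the duplex, and the thermodynamic degree of that uptake, Δn
(ions per duplex), follows from the slope of stability against log₁₀ of
the ion concentration by either of two equivalent relations:

    δ(−ΔG°)/δlog[M]  = 2.303·α·R·T·Δn            (free-energy route)
    δ(Tm⁻¹)/δlog[M]  = 2.303·α·R·Δn/ΔH°          (Tm route, ΔH° constant)

α is an empirical nonideality factor of the salt solution (0.9 for NaCl,
0.88 for MgCl₂); R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹. Mg²⁺ series use the same
linear-in-log formalism with its own α — no additional valence correction.

This module also computes the condition-comparison quantities of mismatch
discrimination work: the stability shift relative to a 30 mM reference
(−ΔG°_salt = ΔG°_ref − ΔG°_obs) and matched-vs-mismatched ΔΔG°37 / ΔTm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .constants import LN10, R_KCAL, T37
from .core import ThermoParams

__all__ = [
    "SaltSeries",
    "SaltSlope",
    "IonUptake",
    "fit_salt_slope",
    "ion_uptake_from_dg",
    "ion_uptake_from_tm",
    "delta_g_salt_shift",
    "discrimination",
    "slope_intercept_correlation",
    "ALPHA_NA",
    "ALPHA_MG",
]

#: Nonideality factors: NaCl and MgCl₂ solutions.
ALPHA_NA = 0.9
ALPHA_MG = 0.88

ValueKind = Literal["minus_dg37", "inv_tm"]


@dataclass(frozen=True)
class SaltSeries:
    """Stability values across a salt titration for one duplex.

    ``points`` are (concentration in M, value) pairs where the value is
    either −ΔG°37 in kcal·mol⁻¹ (``value_kind="minus_dg37"``) or Tm⁻¹ in
    K⁻¹ (``value_kind="inv_tm"``).
    """

    species: str  # "Na+" or "Mg2+"
    points: tuple[tuple[float, float], ...]
    value_kind: ValueKind = "minus_dg37"
    solvent_tag: str = "aqueous"
    label: str = ""

    def __post_init__(self) -> None:
        concs = [p[0] for p in self.points]
        if any(c <= 0 for c in concs):
            raise ValueError("salt concentrations must be positive")
        if len(set(concs)) != len(concs):
            raise ValueError("salt concentrations must be distinct")


@dataclass(frozen=True)
class SaltSlope:
    """OLS line of a stability value on log₁₀[M].

    ``intercept`` is the value extrapolated to 1 M (log₁₀[M] = 0); for a
    −ΔG°37 series it is the 1 M duplex stability.
    """

    slope: float  # per log10 unit (kcal·mol⁻¹ or K⁻¹, per value_kind)
    stderr: float
    intercept: float
    r_squared: float
    value_kind: ValueKind = "minus_dg37"


@dataclass(frozen=True)
class IonUptake:
    """Counterion uptake Δn with the inputs that produced it."""

    delta_n: float  # full precision
    alpha: float
    method: Literal["from_dg", "from_tm_inv"]

    @property
    def delta_n_reported(self) -> float:
        """Δn rounded to one decimal, the conventional reporting precision."""
        return round(self.delta_n, 1)


def fit_salt_slope(series: SaltSeries) -> SaltSlope:
    """Ordinary least squares of the series value on log₁₀(concentration)."""
    if len(series.points) < 3:
        raise ValueError(
            f"salt regression needs >= 3 points, got {len(series.points)}"
        )
    x = np.log10([p[0] for p in series.points])
    y = np.array([p[1] for p in series.points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10 concentration")
    fit = stats.linregress(x, y)
    stderr = float(fit.stderr) if np.isfinite(fit.stderr) else 0.0
    return SaltSlope(
        slope=float(fit.slope),
        stderr=stderr,
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2) if np.ptp(y) > 0 else 1.0,
        value_kind=series.value_kind,
    )


def ion_uptake_from_dg(slope: float, alpha: float, T: float = T37) -> IonUptake:
    """Δn from a −ΔG° salt slope: Δn = slope / (2.303·α·R·T).

    ``slope`` is δ(−ΔG°)/δlog₁₀[M] in kcal·mol⁻¹ per decade at the
    temperature ``T`` of the ΔG° values (default 310.15 K, since duplex
    stabilities are conventionally extrapolated to 37 °C).
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if T <= 0:
        raise ValueError(f"absolute temperature must be positive, got {T}")
    return IonUptake(
        delta_n=slope / (LN10 * alpha * R_KCAL * T), alpha=alpha, method="from_dg"
    )


def ion_uptake_from_tm(slope_tm_inv: float, dH: float, alpha: float) -> IonUptake:
    """Δn from a Tm⁻¹ salt slope: Δn = slope·ΔH° / (2.303·α·R).

    Assumes ΔH° constant over the salt range. The signs compose so that a
    salt-stabilized duplex (Tm rising with [M], hence a negative Tm⁻¹
    slope, and ΔH° < 0) yields a positive Δn.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if dH == 0:
        raise ValueError("dH must be non-zero")
    return IonUptake(
        delta_n=slope_tm_inv * dH / (LN10 * alpha * R_KCAL),
        alpha=alpha,
        method="from_tm_inv",
    )


def delta_g_salt_shift(dg_obs: float, dg_ref_30mM: float) -> float:
    """Stability gained relative to the 30 mM reference condition.

    −ΔG°_salt = ΔG°_ref(30 mM) − ΔG°_obs, both at 37 °C; positive when the
    observed condition is more stable than the reference.
    """
    return dg_ref_30mM - dg_obs


def discrimination(
    params_match: ThermoParams,
    tm_match: float,
    params_mismatch: ThermoParams,
    tm_mismatch: float,
    condition_match: str | None = None,
    condition_mismatch: str | None = None,
) -> tuple[float, float]:
    """Matched-vs-mismatched duplex comparison under one condition.

    Returns ``(ΔΔG°37, ΔTm)`` with ΔΔG°37 = ΔG°37(mismatch) − ΔG°37(match)
    (positive when the matched duplex is more stable) and
    ΔTm = Tm(match) − Tm(mismatch) in K. If condition tags are supplied for
    both duplexes they must agree — comparing across solution conditions is
    a category error, not a discrimination energy.
    """
    if (
        condition_match is not None
        and condition_mismatch is not None
        and condition_match != condition_mismatch
    ):
        raise ValueError(
            f"condition mismatch: {condition_match!r} vs {condition_mismatch!r}"
        )
    ddg = params_mismatch.dG37 - params_match.dG37
    dtm = tm_match - tm_mismatch
    return ddg, dtm


def slope_intercept_correlation(slopes: Sequence[SaltSlope]) -> float:
    """Pearson r between salt slopes and their 1 M intercepts across duplexes.

    A positive correlation says that intrinsically more stable duplexes
    (larger extrapolated 1 M −ΔG°37) also take up more ions on formation.
    """
    if len(slopes) < 3:
        raise ValueError("correlation needs >= 3 duplexes")
    s = np.array([sl.slope for sl in slopes])
    i = np.array([sl.intercept for sl in slopes])
    r, _ = stats.pearsonr(s, i)
    return float(r)


def minus_dg_series_from_params(
    species: str,
    points: Sequence[tuple[float, ThermoParams]],
    solvent_tag: str = "aqueous",
    label: str = "",
) -> SaltSeries:
    """Build a −ΔG°37 salt series from per-concentration parameters."""
    return SaltSeries(
        species=species,
        points=tuple((c, -p.dG37) for c, p in points),
        value_kind="minus_dg37",
        solvent_tag=solvent_tag,
        label=label,
    )


def inv_tm_series_from_params(
    species: str,
    points: Sequence[tuple[float, ThermoParams]],
    Ct: float,
    solvent_tag: str = "aqueous",
    label: str = "",
) -> SaltSeries:
    """Build a Tm⁻¹ salt series at fixed Ct from per-concentration parameters."""
    from .core import melting_temperature

    return SaltSeries(
        species=species,
        points=tuple(
            (c, 1.0 / melting_temperature(p.dH, p.dS, Ct)) for c, p in points
        ),
        value_kind="inv_tm",
        solvent_tag=solvent_tag,
        label=label,
    )
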