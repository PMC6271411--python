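"""Synthetic UV melting curves, strand-concentration series and salt series.

The generator is the two-state analysis model run forward. A melting curve
at 260 nm is modeled as a population-weighted mix of two linear baselines —
the duplex (lower) and single-strand (upper, hyperchromic) baselines — plus
i.i.d. Gaussian photometric noise:

    A(T) = f(T)·(b_ds + m_ds·T) + (1 − f(T))·(b_ss + m_ss·T) + ε

with ``f(T)`` the two-state duplex fraction at the curve's total strand
concentration and ε ~ Normal(0, noise_sd), independently per point.

A strand-concentration series shares one true (ΔH°, ΔS°) across curves, so
its noiseless Tm⁻¹ values are exactly linear in log₁₀(Ct/4). A salt series
keeps ΔH° fixed and makes −ΔG°37 linear in log₁₀[M] — the polyelectrolyte
behavior underlying counterion-uptake analysis — with ΔS° absorbing the
entire salt dependence.

Every stochastic output is driven by the mandatory integer ``seed``;
identical configurations produce identical data. Per-curve noise streams
are spawned from the master seed so that curves within a series are
independent but jointly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .constants import celsius_to_kelvin
from .core import ThermoParams, duplex_fraction, equilibrium_constant

__all__ = [
    "SolutionCondition",
    "MeltingCurve",
    "SaltModel",
    "SimulationConfig",
    "generate_melting_curve",
    "generate_ct_series",
    "generate_salt_series",
]

MIN_CURVE_POINTS = 20


@dataclass(frozen=True)
class SolutionCondition:
    """Salt and solvent of a measurement: species, concentration, ethanol."""

    salt_species: str = "Na+"  # "Na+" or "Mg2+"
    salt_conc_M: float = 1.0
    ethanol_M: float = 0.0

    @property
    def tag(self) -> str:
        eth = f"+EtOH{self.ethanol_M:g}M" if self.ethanol_M else ""
        return f"{self.salt_species}:{self.salt_conc_M:g}M{eth}"


@dataclass(frozen=True)
class MeltingCurve:
    """A temperature/absorbance series with its measurement conditions.

    ``temperatures`` are in °C on a strictly increasing grid of at least 20
    points; ``Ct`` is the TOTAL single-strand concentration in M.
    """

    temperatures: np.ndarray
    absorbance: np.ndarray
    Ct: float
    condition: SolutionCondition = SolutionCondition()
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "absorbance", a)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("temperatures and absorbance must be 1-D and equal length")
        if t.size < MIN_CURVE_POINTS:
            raise ValueError(
                f"melting curve needs >= {MIN_CURVE_POINTS} points, got {t.size}"
            )
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance contains non-finite values")
        if not self.Ct > 0:
            raise ValueError(f"Ct must be positive, got {self.Ct}")

    @property
    def temperatures_K(self) -> np.ndarray:
        return self.temperatures + 273.15


@dataclass(frozen=True)
class SaltModel:
    """Linear-in-log[M] stability model with salt-independent ΔH°.

    ``minus_dg37_1M`` is −ΔG°37 extrapolated to 1 M (the intercept at
    log₁₀[M] = 0, kcal·mol⁻¹); ``slope`` is δ(−ΔG°37)/δlog₁₀[M]
    (kcal·mol⁻¹ per decade, positive for salt-stabilized duplexes);
    ``alpha`` is the empirical nonideality factor of the salt solution.
    """

    minus_dg37_1M: float
    slope: float
    alpha: float = 0.9
    species: str = "Na+"
    ethanol_M: float = 0.0

    def params_at(self, conc_M: float, dH: float) -> ThermoParams:
        """True (ΔH°, ΔS°) at salt concentration ``conc_M``."""
        if conc_M <= 0:
            raise ValueError(f"salt concentration must be positive, got {conc_M}")
        minus_dg = self.minus_dg37_1M + self.slope * math.log10(conc_M)
        return ThermoParams.from_dh_dg37(dH=dH, dG37=-minus_dg)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one duplex's synthetic data.

    Baselines: ``b_ds``/``m_ds`` are the duplex-baseline intercept
    (absorbance at 0 °C) and slope (per °C); ``b_ss``/``m_ss`` the
    single-strand baseline. The single-strand baseline must lie above the
    duplex baseline across the grid (melting is hyperchromic at 260 nm).
    """

    truth: ThermoParams
    b_ds: float = 0.60
    m_ds: float = 2e-4
    b_ss: float = 0.75
    m_ss: float = 3e-4
    noise_sd: float = 0.0
    t_start: float = 0.0
    t_stop: float = 95.0
    t_step: float = 0.5
    Ct_list: tuple[float, ...] = (2e-6, 1e-5, 5e-5, 2e-4)
    salt_model: SaltModel | None = None
    condition: SolutionCondition = SolutionCondition()
    label: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if self.t_step <= 0 or self.t_stop <= self.t_start:
            raise ValueError("temperature grid must be increasing with positive step")
        grid = self.temperature_grid()
        low = self.b_ds + self.m_ds * grid
        high = self.b_ss + self.m_ss * grid
        if not np.all(high > low):
            raise ValueError(
                "single-strand baseline must lie above the duplex baseline "
                "across the temperature grid (hyperchromicity)"
            )

    def temperature_grid(self) -> np.ndarray:
        n = int(round((self.t_stop - self.t_start) / self.t_step)) + 1
        return self.t_start + self.t_step * np.arange(n)


def _duplex_fraction_curve(truth: ThermoParams, Ct: float, t_celsius: np.ndarray) -> np.ndarray:
    t_kelvin = celsius_to_kelvin(t_celsius)
    return np.array(
        [duplex_fraction(equilibrium_constant(truth.dG(tk), tk), Ct) for tk in t_kelvin]
    )


def noiseless_absorbance(config: SimulationConfig, Ct: float) -> np.ndarray:
    """The deterministic part of the generated curve at the config grid."""
    t = config.temperature_grid()
    f = _duplex_fraction_curve(config.truth, Ct, t)
    lower = config.b_ds + config.m_ds * t
    upper = config.b_ss + config.m_ss * t
    return f * lower + (1.0 - f) * upper


def generate_melting_curve(
    config: SimulationConfig,
    Ct: float,
    rng: np.random.Generator | None = None,
) -> MeltingCurve:
    """Generate one melting curve at total strand concentration ``Ct``.

    The noiseless transition midpoint is exactly
    ``melting_temperature(truth.dH, truth.dS, Ct)``. When ``rng`` is not
    given, a fresh generator is created from ``config.seed``.
    """
    t = config.temperature_grid()
    if t.size < MIN_CURVE_POINTS:
        raise ValueError(
            f"temperature grid too sparse: {t.size} points < {MIN_CURVE_POINTS}"
        )
    a = noiseless_absorbance(config, Ct)
    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        a = a + rng.normal(0.0, config.noise_sd, size=a.shape)
    return MeltingCurve(
        temperatures=t,
        absorbance=a,
        Ct=Ct,
        condition=config.condition,
        label=config.label or f"synthetic Ct={Ct:g}M seed={config.seed}",
    )


def generate_ct_series(config: SimulationConfig) -> list[MeltingCurve]:
    """One curve per concentration in ``config.Ct_list``, shared truth.

    Because every curve shares (ΔH°, ΔS°), the noiseless Tm⁻¹ values are
    exactly linear in log₁₀(Ct/4) — the van't Hoff concentration design.
    Requires at least two distinct concentrations.
    """
    cts = tuple(config.Ct_list)
    if len(set(cts)) < 2:
        raise ValueError("a concentration series needs >= 2 distinct Ct values")
    streams = np.random.SeedSequence(config.seed).spawn(len(cts))
    return [
        generate_melting_curve(config, ct, rng=np.random.default_rng(stream))
        for ct, stream in zip(cts, streams)
    ]


def generate_salt_series(
    config: SimulationConfig,
    concentrations: tuple[float, ...] = (0.03, 0.1, 0.3, 1.0),
) -> list[tuple[float, ThermoParams]]:
    """True thermodynamic parameters across a salt series.

    −ΔG°37 is linear in log₁₀[M] with the configured slope and 1 M
    intercept; ΔH° = ``config.truth.dH`` at every concentration (the
    standard constant-enthalpy assumption), so ΔS° carries the salt
    dependence. Requires ``config.salt_model`` and >= 3 concentrations.
    """
    if config.salt_model is None:
        raise ValueError("config.salt_model is required for a salt series")
    if len(concentrations) < 3:
        raise ValueError("a salt series needs >= 3 concentrations")
    if any(c <= 0 for c in concentrations):
        raise ValueError("salt concentrations must be positive")
    model = config.salt_model
    return [(c, model.params_at(c, dH=config.truth.dH)) for c in concentrations]


def config_for_salt(config: SimulationConfig, conc_M: float) -> SimulationConfig:
    """Specialize a config to one salt concentration of its salt model."""
    if config.salt_model is None:
        raise ValueError("config.salt_model is required")
    model = config.salt_model
    truth = model.params_at(conc_M, dH=config.truth.dH)
    condition = SolutionCondition(
        salt_species=model.species, salt_conc_M=conc_M, ethanol_M=model.ethanol_M
    )
    return replace(config, truth=truth, condition=condition)
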