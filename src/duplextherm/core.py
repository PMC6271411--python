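"""Two-state equilibrium thermodynamics of bimolecular DNA duplex formation.

The model: two non-identical complementary strands A and B, each present at
``Ct/2`` (``Ct`` is the TOTAL single-strand concentration, both strands
summed), associate into a heteroduplex AB with equilibrium constant

    K = [AB] / ([A][B])        (M⁻¹)

Everything downstream — melting-curve fitting, van't Hoff concentration
analysis, salt-dependence slopes — reduces to the three functions here plus
ordinary least squares.

.. warning::
   The ``Ct`` convention is TOTAL strand concentration. Each strand is at
   ``Ct/2``, which is what makes ``K(Tm) = 4/Ct`` and the ``ln(Ct/4)`` form
   of the melting-temperature equation correct for non-self-complementary
   duplexes. Passing a per-strand concentration silently shifts Tm by
   ``R·ln 2`` worth of entropy — the classic factor-of-two bug.

Only the bimolecular, non-self-complementary case is implemented; a
self-complementary strand folds into the ``K(Tm) = 1/Ct`` molecularity and
is rejected explicitly where sequences are validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import R_CAL, R_KCAL, T37

__all__ = [
    "ThermoParams",
    "EquilibriumState",
    "gibbs_free_energy",
    "equilibrium_constant",
    "duplex_fraction",
    "melting_temperature",
]


@dataclass(frozen=True)
class ThermoParams:
    """Standard-state thermodynamic parameters of duplex formation.

    Attributes
    ----------
    dH : float
        Enthalpy change in kcal·mol⁻¹ (negative for duplex formation).
    dS : float
        Entropy change in cal·mol⁻¹·K⁻¹ (note the cal/kcal factor of 1000).

    ``dG37`` is derived from ``dH`` and ``dS`` rather than stored, so the
    triple is self-consistent by construction.
    """

    dH: float
    dS: float

    @property
    def dG37(self) -> float:
        """ΔG° at 37 °C (310.15 K), kcal·mol⁻¹."""
        return gibbs_free_energy(self.dH, self.dS, T37)

    def dG(self, T: float) -> float:
        """ΔG° at absolute temperature ``T``, kcal·mol⁻¹."""
        return gibbs_free_energy(self.dH, self.dS, T)

    @classmethod
    def from_dh_dg37(cls, dH: float, dG37: float) -> "ThermoParams":
        """Build parameters from ΔH° and ΔG°37, solving for ΔS°."""
        return cls(dH=dH, dS=(dH - dG37) * 1000.0 / T37)

    def __add__(self, other: "ThermoParams") -> "ThermoParams":
        return ThermoParams(self.dH + other.dH, self.dS + other.dS)

    def __sub__(self, other: "ThermoParams") -> "ThermoParams":
        return ThermoParams(self.dH - other.dH, self.dS - other.dS)


@dataclass(frozen=True)
class EquilibriumState:
    """A solved mass-action state of the two-strand system."""

    K: float  # association constant, M⁻¹
    f: float  # fraction of strands in duplex
    Ct: float  # total single-strand concentration, M
    T: float  # absolute temperature, K


def gibbs_free_energy(dH: float, dS: float, T: float) -> float:
    """ΔG°(T) = ΔH° − T·ΔS°/1000, with ΔH° in kcal and ΔS° in cal units.

    Parameters
    ----------
    dH : kcal·mol⁻¹
    dS : cal·mol⁻¹·K⁻¹
    T : K, must be positive

    Returns
    -------
    float
        ΔG°(T) in kcal·mol⁻¹.
    """
    if T <= 0:
        raise ValueError(f"absolute temperature must be positive, got {T}")
    return dH - T * dS / 1000.0


def equilibrium_constant(dG: float, T: float) -> float:
    """Association constant K = exp(−ΔG°/(R·T)) in M⁻¹."""
    if T <= 0:
        raise ValueError(f"absolute temperature must be positive, got {T}")
    return math.exp(-dG / (R_KCAL * T))


def duplex_fraction(K: float, Ct: float) -> float:
    """Fraction of strands in duplex at association constant ``K``.

    Solves the mass-action law for two strands each at ``Ct/2``:

        K·Ct·f² − 2(K·Ct + 1)·f + K·Ct = 0

    and returns the physical (smaller) root, f ∈ [0, 1]. The root is
    evaluated in the rationalized form ``f = a / (a + 1 + sqrt(2a + 1))``
    with ``a = K·Ct``, which avoids the catastrophic cancellation of the
    textbook quadratic formula when ``a`` is small.
    """
    if K < 0:
        raise ValueError(f"equilibrium constant must be non-negative, got {K}")
    if Ct <= 0:
        raise ValueError(f"total strand concentration must be positive, got {Ct}")
    a = K * Ct
    if a == 0.0:
        return 0.0
    if math.isinf(a):
        return 1.0
    return a / (a + 1.0 + math.sqrt(2.0 * a + 1.0))


def melting_temperature(dH: float, dS: float, Ct: float) -> float:
    """Closed-form Tm (K) of a non-self-complementary duplex.

    At the melting temperature half the strands are paired, which for the
    bimolecular equilibrium means ``K(Tm) = 4/Ct``. Substituting
    ΔG°(Tm) = −R·Tm·ln(4/Ct) gives

        Tm = 1000·ΔH° / (ΔS° + R·ln(Ct/4))      (R = 1.987 cal·mol⁻¹·K⁻¹)

    Parameters must describe a duplex that actually melts: ΔH° < 0 and a
    negative denominator, otherwise a ``ValueError`` is raised.
    """
    if Ct <= 0:
        raise ValueError(f"total strand concentration must be positive, got {Ct}")
    if dH >= 0:
        raise ValueError(f"duplex formation requires dH < 0, got {dH}")
    denom = dS + R_CAL * math.log(Ct / 4.0)
    if denom >= 0:
        raise ValueError(
            f"no finite positive melting temperature: dS + R·ln(Ct/4) = {denom:.4g} >= 0"
        )
    return 1000.0 * dH / denom
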