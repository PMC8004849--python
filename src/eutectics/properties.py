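"""Empirical physical-property correlations for eutectic solvent mixtures.

Corresponding-states-style correlations estimate the liquid density,
surface tension and refractive index of a binary eutectic mixture from its
pseudocritical properties (Tc, Pc, Vc), acentric factor and molecular
weight.  The correlation constants (sigma1..sigma6, a1..a9) are frozen to
the published fitted values; several carry units that make individual terms
dimensionless.

The density correlation is

    rho_L = -1.13e-6*Tc**2 + 2.566e-3*Tc + 0.2376*omega**0.2211
            - 4.67e-4*Vc - 4.64e-4*T        [g/mL; Tc, T in K; Vc cm3/mol]

The surface-tension correlation as typeset in the source admits more than
one term grouping once flattened; see :func:`surface_tension_eq2` for the
two implemented readings.  The refractive-index correlation is

    n = a5*omega**3 + a6*omega**2/Mw + a7*Pc + a8 + a9*omega/T

(the a6 term is read as per-Mw, the only reading that yields physical
values; the printed unit label "mol/g" is then a g/mol transposition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .compounds import BinarySystem, P_REF
from .critical import CriticalProps, LJRGroupTable, mixture_critical_properties


@dataclass(frozen=True)
class CorrelationConstants:
    """Fitted constants of the surface-tension / refractive-index models.

    sigma1..sigma6 in mN/m; a1..a4 are unit-carrying 1-valued conversion
    constants; a5..a9 as published (a7 in 1/bar, a9 in K).
    """

    sigma1: float = 393.4
    sigma2: float = -5.3e-5
    sigma3: float = -3.72e-2
    sigma4: float = -50.3
    sigma5: float = 1.132
    sigma6: float = 108.9
    a1: float = 1.0
    a2: float = 1.0
    a3: float = 1.0
    a4: float = 1.0
    a5: float = 5.17e-2
    a6: float = -11.625
    a7: float = 2.27e-3
    a8: float = 1.3668
    a9: float = 25.89


DEFAULT_CONSTANTS = CorrelationConstants()


class CorrelationDomainError(ValueError):
    """An input left the domain of a correlation (e.g. log of non-positive)."""


def density_eq1(cp: CriticalProps, t: float) -> float:
    """Liquid density of the mixture, g/mL.

    Exactly linear in T and Vc; the acentric factor enters through a
    fractional power, so omega must be positive.
    """
    if t <= 0:
        raise CorrelationDomainError("temperature must be positive")
    if cp.omega is None or cp.omega <= 0:
        raise CorrelationDomainError(
            "density correlation needs omega > 0 (fractional power)")
    return (-1.13e-6 * cp.t_c ** 2 + 2.566e-3 * cp.t_c
            + 0.2376 * cp.omega ** 0.2211 - 4.67e-4 * cp.v_c - 4.64e-4 * t)


def surface_tension_eq2(
    cp: CriticalProps,
    mw: float,
    rho: float,
    t: float,
    k: CorrelationConstants = DEFAULT_CONSTANTS,
    grouping: str = "empirical",
) -> float:
    """Surface tension of the mixture, mN/m.

    Two readings of the flattened published expression are implemented;
    both share

        sigma1*ln(rho) + sigma2*omega*Pc/Pref
        + sigma3*Tc*ln(a1*rho**2*(Vc + sigma4*a2*omega**2)) + ... + sigma6

    and differ in the mixed Mw/T/Pc term:

    - ``"dimensional"``: sigma5*a3*Mw*sqrt(T)/Pc * ln(Vc*rho*a4/sqrt(T)),
      the unique grouping under which the unit-carrying constants a3, a4
      cancel all units.
    - ``"empirical"`` (default): sigma5*a3*Mw/Pc * ln(Vc*rho*a4*sqrt(T)),
      the grouping that comes closest to the published theoretical values
      for the four terpene systems.  Neither reading reproduces those
      values exactly; see docs/methods.md.
    """
    if cp.omega is None:
        raise CorrelationDomainError("surface tension needs omega")
    if rho <= 0:
        raise CorrelationDomainError("density must be positive (ln rho term)")
    bracket = cp.v_c + k.sigma4 * k.a2 * cp.omega ** 2
    arg3 = k.a1 * rho ** 2 * bracket
    if arg3 <= 0:
        raise CorrelationDomainError(
            f"size term log argument non-positive ({arg3:.4g}); "
            f"Vc + sigma4*a2*omega^2 = {bracket:.4g}")
    sqrt_t = math.sqrt(t)
    if grouping == "dimensional":
        arg4 = cp.v_c * rho * k.a4 / sqrt_t
        mix_term = k.sigma5 * k.a3 * mw * sqrt_t / cp.p_c * math.log(arg4)
    elif grouping == "empirical":
        arg4 = cp.v_c * rho * k.a4 * sqrt_t
        mix_term = k.sigma5 * k.a3 * mw / cp.p_c * math.log(arg4)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    if arg4 <= 0:
        raise CorrelationDomainError("mixed-term log argument non-positive")
    return (k.sigma1 * math.log(rho)
            + k.sigma2 * cp.omega * cp.p_c / P_REF
            + k.sigma3 * cp.t_c * math.log(arg3)
            + mix_term
            + k.sigma6)


def refractive_index_eq3(
    cp: CriticalProps,
    mw: float,
    t: float,
    k: CorrelationConstants = DEFAULT_CONSTANTS,
) -> float:
    """Refractive index (dimensionless) of the mixture at temperature t."""
    if t <= 0:
        raise CorrelationDomainError("temperature must be positive")
    if cp.omega is None:
        raise CorrelationDomainError("refractive index needs omega")
    w = cp.omega
    return (k.a5 * w ** 3 + k.a6 * w ** 2 / mw + k.a7 * cp.p_c + k.a8
            + k.a9 * w / t)


def mixture_mw_eq4(mw_i: float, mw_j: float, x_i: float, x_j: float) -> float:
    """Mole-fraction-averaged molecular weight, g/mol."""
    if x_i + x_j <= 0:
        raise ValueError("at least one mole fraction must be positive")
    return (x_i * mw_i + x_j * mw_j) / (x_i + x_j)


def relative_error_eq5(theoretical: float, experimental: float) -> float:
    """Percentage relative error, 100*(theoretical-experimental)/experimental."""
    if experimental == 0:
        raise ZeroDivisionError("experimental value must be nonzero")
    return 100.0 * (theoretical - experimental) / experimental


@dataclass(frozen=True)
class PropertyValue:
    """One property: theoretical estimate, optional measurement, e_r (%)."""

    theoretical: float
    experimental: float | None = None
    e_r: float | None = None


@dataclass(frozen=True)
class PropertyReport:
    """Theoretical vs experimental density, surface tension and refractive
    index for one binary system at one temperature."""

    system: str
    t: float
    mw: float
    critical: CriticalProps
    density: PropertyValue
    surface_tension: PropertyValue
    refractive_index: PropertyValue

    def as_dict(self) -> dict:
        out: dict = {"system": self.system, "T_K": self.t,
                     "Mw_g_per_mol": self.mw}
        for key, pv, nd in (("density_g_per_mL", self.density, 4),
                            ("surface_tension_mN_per_m",
                             self.surface_tension, 2),
                            ("refractive_index", self.refractive_index, 4)):
            out[key] = round(pv.theoretical, nd)
            if pv.experimental is not None:
                out[key + "_exp"] = pv.experimental
                out[key + "_er_pct"] = round(pv.e_r, 2)
        return out


def _value(theoretical: float, experimental: float | None) -> PropertyValue:
    if experimental is None:
        return PropertyValue(theoretical=theoretical)
    return PropertyValue(theoretical=theoretical, experimental=experimental,
                         e_r=relative_error_eq5(theoretical, experimental))


def property_report(
    system: BinarySystem,
    t: float,
    experimental: Mapping[str, float] | None = None,
    table: LJRGroupTable | None = None,
    k: CorrelationConstants = DEFAULT_CONSTANTS,
    grouping: str = "empirical",
    measured_density: float | None = None,
) -> PropertyReport:
    """Full theoretical property report for a binary system.

    ``experimental`` may carry keys ``density``, ``surface_tension``,
    ``refractive_index``; an e_r is attached for each one supplied.  The
    density fed into the surface-tension correlation is the theoretical one
    unless ``measured_density`` is given.
    """
    experimental = experimental or {}
    cp = mixture_critical_properties(
        [(system.comp_i, system.x_i), (system.comp_j, system.x_j)], table)
    mw = mixture_mw_eq4(system.comp_i.mw, system.comp_j.mw,
                        system.x_i, system.x_j)
    rho = density_eq1(cp, t)
    sigma = surface_tension_eq2(
        cp, mw, measured_density if measured_density is not None else rho,
        t, k, grouping)
    n = refractive_index_eq3(cp, mw, t, k)
    return PropertyReport(
        system=system.label, t=t, mw=mw, critical=cp,
        density=_value(rho, experimental.get("density")),
        surface_tension=_value(sigma, experimental.get("surface_tension")),
        refractive_index=_value(n, experimental.get("refractive_index")),
    )
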