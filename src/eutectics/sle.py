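"""Solid-liquid equilibrium: liquidus curves, eutectic points, deep-eutectic
classification.

Each liquidus branch obeys the simplified melting-equilibrium relation
(heat-capacity change on fusion neglected)

    ln(x_i * gamma_i) = (dH_fus / R) * (1/T_fus - 1/T)

for the component in equilibrium with its pure solid.  The eutectic is the
temperature at which the two branch compositions sum to one.  For the
ideal model (gamma = 1) the branch composition has a closed form; for a
non-ideal activity model the inner composition solve uses damped
successive substitution and the outer temperature solve bracketed Brent
iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .activity import ActivityModel, IdealSolution
from .compounds import BinarySystem, Compound, R_GAS

#: Default lower bound of the eutectic temperature search, K.  Sub-200 K
#: eutectics occur for strongly non-ideal pairs, so the floor sits well
#: below any fixture melting point.
T_FLOOR_DEFAULT = 150.0

#: Residual tolerance on ln(x*gamma) - RHS at a converged point.
RESIDUAL_TOL = 1e-10

_DAMPING = 0.5
_MAX_ITER = 200


class SolverError(RuntimeError):
    """Liquidus or eutectic solve failed (no root or no convergence)."""


def _liquidus_rhs(component: Compound, t: float) -> float:
    """(dH_fus/R)(1/T_fus - 1/T); <= 0 for t <= T_fus."""
    return component.dh_fus_J / R_GAS * (1.0 / component.t_fus - 1.0 / t)


def liquidus_x_at_t(
    component: Compound,
    t: float,
    other: Compound,
    model: ActivityModel | None = None,
) -> float:
    """Mole fraction of ``component`` on its liquidus branch at ``t``.

    Solves ln(x*gamma(x, t)) = (dH_fus/R)(1/T_fus - 1/T) for x in (0, 1].
    The activity model is evaluated on the ordered pair
    (component, other) with composition (x, 1-x).
    """
    model = model or IdealSolution()
    if not 0.0 < t <= component.t_fus:
        raise SolverError(
            f"{component.name}: liquidus defined for 0 < T <= T_fus "
            f"({component.t_fus} K), got {t} K")
    rhs = _liquidus_rhs(component, t)
    x = min(math.exp(rhs), 1.0)  # ideal solution: closed form
    if isinstance(model, IdealSolution):
        return x
    comps = (component, other)

    def residual(x_val: float) -> float:
        gamma = float(model.gamma([x_val, 1.0 - x_val], t, comps)[0])
        return math.log(x_val * gamma) - rhs

    # damped successive substitution from the ideal starting point
    ok = True
    for _ in range(_MAX_ITER):
        gamma = float(model.gamma([x, 1.0 - x], t, comps)[0])
        x_new = math.exp(rhs) / gamma
        if not 0.0 < x_new <= 1.0:
            ok = False
            break  # iterate left (0, 1]; fall back to bracketing
        x = (1.0 - _DAMPING) * x + _DAMPING * x_new
        if abs(residual(x)) < RESIDUAL_TOL:
            return x
    if ok and abs(residual(x)) < 1e-8:
        return x

    # bracketed fallback: residual(1) = -rhs >= 0 and residual -> -inf as
    # x -> 0, so scan downward from x = 1 for the sign change nearest the
    # pure limit (the physically meaningful liquidus root)
    x_hi, f_hi = 1.0, residual(1.0)
    if abs(f_hi) < RESIDUAL_TOL:
        return 1.0
    for x_lo in np.geomspace(1.0, 1e-12, 240)[1:]:
        f_lo = residual(float(x_lo))
        if f_lo == 0.0:
            return float(x_lo)
        if f_lo * f_hi < 0:
            return brentq(residual, float(x_lo), x_hi, xtol=1e-15,
                          rtol=8.9e-16)
        x_hi, f_hi = float(x_lo), f_lo
    raise SolverError(
        f"{component.name} liquidus at {t} K has no root in (0, 1] "
        f"(residual at brackets: {residual(1e-12):.3g}, {residual(1.0):.3g})")


def liquidus_t_at_x(
    component: Compound,
    x: float,
    other: Compound,
    model: ActivityModel | None = None,
    t_floor: float = T_FLOOR_DEFAULT,
) -> float:
    """Liquidus temperature of ``component`` at liquid mole fraction ``x``."""
    model = model or IdealSolution()
    if not 0.0 < x <= 1.0:
        raise SolverError("x must lie in (0, 1]")
    if isinstance(model, IdealSolution):
        inv_t = 1.0 / component.t_fus - R_GAS * math.log(x) / component.dh_fus_J
        return 1.0 / inv_t

    def f(t: float) -> float:
        gamma = float(model.gamma([x, 1.0 - x], t, (component, other))[0])
        return math.log(x * gamma) - _liquidus_rhs(component, t)

    lo, hi = t_floor, component.t_fus
    f_hi = f(hi)
    if abs(f_hi) < RESIDUAL_TOL:
        return hi
    f_lo = f(lo)
    if f_lo * f_hi > 0:
        raise SolverError(
            f"{component.name}: no liquidus temperature in "
            f"[{t_floor}, T_fus] for x={x} (f={f_lo:.3g}, {f_hi:.3g})")
    return brentq(f, lo, hi, xtol=1e-8)


@dataclass(frozen=True)
class EutecticPoint:
    """Intersection of the two liquidus branches.

    x_e is the mole fraction of the system's first-listed component
    (comp_i); residuals are the two ln(x*gamma) - RHS values at the point.
    """

    x_e: float
    t_e: float
    model: str
    converged: bool
    residuals: tuple[float, float]
    system: str = ""

    def as_dict(self) -> dict:
        return {"system": self.system, "model": self.model,
                "x_E": self.x_e, "T_E_K": self.t_e,
                "converged": self.converged,
                "residual_i": self.residuals[0],
                "residual_j": self.residuals[1]}


def _branch_sum(system: BinarySystem, t: float,
                model: ActivityModel) -> tuple[float, float, float]:
    x_i = liquidus_x_at_t(system.comp_i, t, system.comp_j, model)
    x_j = liquidus_x_at_t(system.comp_j, t, system.comp_i, model)
    return x_i, x_j, x_i + x_j - 1.0


def find_eutectic(
    system: BinarySystem,
    model: ActivityModel | None = None,
    t_floor: float = T_FLOOR_DEFAULT,
) -> EutecticPoint:
    """Locate the eutectic point of a binary system.

    Brackets the root of f(T) = x_i(T) + x_j(T) - 1 on
    [t_floor, min(T_fus)) and refines it by Brent iteration; the returned
    point satisfies both liquidus relations to ~1e-8.
    """
    model = model or IdealSolution()
    t_hi = min(system.comp_i.t_fus, system.comp_j.t_fus) * (1.0 - 1e-9)
    f_hi = _branch_sum(system, t_hi, model)[2]
    if f_hi < 0:
        raise SolverError(
            f"{system.label}: branch fractions sum below 1 even at the "
            f"lower melting point; no simple eutectic")
    # walk down until the branch sum drops below 1
    t_lo = None
    for t in np.linspace(t_hi, t_floor, 60)[1:]:
        try:
            f_t = _branch_sum(system, t, model)[2]
        except SolverError:
            break
        if f_t < 0:
            t_lo = t
            break
        t_hi, f_hi = t, f_t
    if t_lo is None:
        raise SolverError(
            f"{system.label}: liquidus branches do not cross above the "
            f"temperature floor ({t_floor} K); lower t_floor if a deep "
            f"eutectic is expected")
    t_e = brentq(lambda t: _branch_sum(system, t, model)[2],
                 t_lo, t_hi, xtol=1e-8)
    x_i, x_j, gap = _branch_sum(system, t_e, model)
    g = model.gamma([x_i, 1.0 - x_i], t_e, system.compounds)
    res_i = math.log(x_i * float(g[0])) - _liquidus_rhs(system.comp_i, t_e)
    g2 = model.gamma([1.0 - x_j, x_j], t_e, system.compounds)
    res_j = math.log(x_j * float(g2[1])) - _liquidus_rhs(system.comp_j, t_e)
    converged = abs(gap) < 1e-6 and max(abs(res_i), abs(res_j)) < 1e-8
    return EutecticPoint(x_e=x_i, t_e=t_e, model=model.name,
                         converged=converged, residuals=(res_i, res_j),
                         system=system.label)


@dataclass(frozen=True)
class LiquidusBranch:
    """Tabulated liquidus of one component: (x of that component, T)."""

    component: str
    model: str
    samples: tuple[tuple[float, float], ...]  # sorted by x

    def as_rows(self, system: str, branch: str) -> list[dict]:
        return [{"system": system, "model": self.model, "branch": branch,
                 "component": self.component, "x": x, "T_K": t}
                for x, t in self.samples]


@dataclass(frozen=True)
class PhaseDiagram:
    """Two liquidus branches plus the eutectic point for one model."""

    system: BinarySystem
    model: str
    branch_i: LiquidusBranch
    branch_j: LiquidusBranch
    eutectic: EutecticPoint

    def as_rows(self) -> list[dict]:
        return (self.branch_i.as_rows(self.system.label, "i")
                + self.branch_j.as_rows(self.system.label, "j"))


def phase_diagram(
    system: BinarySystem,
    model: ActivityModel | None = None,
    x_grid: Sequence[float] | None = None,
    t_floor: float = T_FLOOR_DEFAULT,
) -> PhaseDiagram:
    """Tabulate both liquidus branches on an x grid and attach the eutectic.

    The grid refers to the mole fraction of each branch's own component;
    points below the eutectic composition of the branch are kept only while
    a liquidus temperature above the floor exists.
    """
    model = model or IdealSolution()
    if x_grid is None:
        x_grid = np.linspace(0.01, 1.0, 100)
    x_grid = sorted(float(x) for x in x_grid)
    if not all(0.0 < x <= 1.0 for x in x_grid):
        raise SolverError("x grid must lie within (0, 1]")
    eut = find_eutectic(system, model, t_floor)
    branches = []
    for comp, other in ((system.comp_i, system.comp_j),
                        (system.comp_j, system.comp_i)):
        samples = []
        for x in x_grid:
            try:
                samples.append((x, liquidus_t_at_x(comp, x, other, model,
                                                   t_floor)))
            except SolverError:
                continue
        branches.append(LiquidusBranch(component=comp.name, model=model.name,
                                       samples=tuple(samples)))
    return PhaseDiagram(system=system, model=model.name,
                        branch_i=branches[0], branch_j=branches[1],
                        eutectic=eut)


#: Classification labels for the real-vs-ideal eutectic comparison.
NEGATIVE_DEVIATION = "negative deviation (DES candidate)"
IDEAL_LIKE = "~ideal"
POSITIVE_DEVIATION = "positive deviation"


def classify_deep(t_e_real: float, t_e_ideal: float,
                  tolerance: float = 0.5) -> str:
    """Deep-eutectic check: is the real eutectic below the ideal one?

    A mixture qualifies as a deep-eutectic candidate when
    T_E,real < T_E,ideal - tolerance (default 0.5 K); symmetric logic
    flags a positive deviation, anything within the band is ~ideal.
    """
    if not (math.isfinite(t_e_real) and math.isfinite(t_e_ideal)):
        raise ValueError("eutectic temperatures must be finite")
    if t_e_real < t_e_ideal - tolerance:
        return NEGATIVE_DEVIATION
    if t_e_real > t_e_ideal + tolerance:
        return POSITIVE_DEVIATION
    return IDEAL_LIKE
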