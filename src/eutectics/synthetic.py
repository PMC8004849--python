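"""Synthetic systems, analytic activity models and brute-force oracles.

Everything here is deterministic in (spec, seed) and exists so that the
solvers can be exercised against independent ground truth without any
external data: random binary systems with melting properties drawn from
realistic terpene-like ranges, the two-parameter Margules model (an
analytic non-ideal activity model with closed-form coefficients and a
tunable deviation sign), a dense grid-scan eutectic locator, and noisy
linear NMR shift series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .compounds import BinarySystem, Compound, R_GAS
from .nmr import NMRSeries
from .sle import EutecticPoint, SolverError, _liquidus_rhs


@dataclass(frozen=True)
class SyntheticSystemSpec:
    """Ranges for fabricated binary systems.

    Melting points span the fixture terpenes' neighbourhood (300-490 K)
    and fusion enthalpies the 5-20 kJ/mol window typical of monoterpene
    crystals.  activity selects the generated metadata tag only; the model
    object used in a test is supplied by the caller.
    """

    t_fus_range: tuple[float, float] = (300.0, 490.0)
    dh_fus_range: tuple[float, float] = (5.0, 20.0)  # kJ/mol
    activity: str = "ideal"  # "ideal" or "margules"

    def __post_init__(self) -> None:
        for lo, hi in (self.t_fus_range, self.dh_fus_range):
            if not 0 < lo <= hi:
                raise ValueError("ranges must be positive and ordered")


def generate_system(spec: SyntheticSystemSpec, seed: int,
                    label: str | None = None) -> BinarySystem:
    """Fabricate a deterministic binary system from a spec and seed."""
    rng = np.random.default_rng(seed)
    t_fus = rng.uniform(*spec.t_fus_range, size=2)
    dh_fus = rng.uniform(*spec.dh_fus_range, size=2)
    comps = [
        Compound(
            name=f"synthetic-{seed}-{k}",
            formula={},
            mw=float(rng.uniform(120.0, 200.0)),
            t_fus=float(t_fus[k]),
            dh_fus=float(dh_fus[k]),
        )
        for k in range(2)
    ]
    return BinarySystem(comp_i=comps[0], comp_j=comps[1],
                        x_i=0.5, label=label or f"synthetic-{seed}")


def margules_gamma(x: Sequence[float], t: float,
                   a12: float, a21: float) -> np.ndarray:
    """Two-parameter Margules activity coefficients.

    RT ln g1 = (A12 + 2 (A21 - A12) x1) x2^2
    RT ln g2 = (A21 + 2 (A12 - A21) x2) x1^2,   A in J/mol.
    """
    x = np.asarray(x, dtype=float)
    if not np.isclose(x.sum(), 1.0, atol=1e-8):
        raise ValueError("composition must sum to 1")
    x1, x2 = x
    rt = R_GAS * t
    ln_g1 = (a12 + 2.0 * (a21 - a12) * x1) * x2 ** 2 / rt
    ln_g2 = (a21 + 2.0 * (a12 - a21) * x2) * x1 ** 2 / rt
    return np.exp([ln_g1, ln_g2])


@dataclass(frozen=True)
class MargulesActivity:
    """ActivityModel wrapper around :func:`margules_gamma` (test oracle).

    A12 belongs to the component named ``first_component`` (A21 to the
    other); when the caller passes the compounds in the opposite order the
    composition and result are swapped accordingly, so the model is safe
    to use with branch solvers that reorder the pair.  With
    ``first_component=None`` the given order is taken at face value.
    """

    a12: float
    a21: float
    first_component: str | None = None
    name: str = "margules"

    def _swapped(self, compounds: Sequence[Compound]) -> bool:
        return (self.first_component is not None and len(compounds) == 2
                and compounds[0].name != self.first_component)

    def gamma(self, x: Sequence[float], t: float,
              compounds: Sequence[Compound] = ()) -> np.ndarray:
        if self._swapped(compounds):
            return margules_gamma([x[1], x[0]], t, self.a12, self.a21)[::-1]
        return margules_gamma(x, t, self.a12, self.a21)


def _gamma_grid(model, xs: np.ndarray, t: float, comps) -> np.ndarray:
    """Activity coefficients for a whole composition grid, shape (n, 2).

    Closed-form models (ideal, Margules) are evaluated vectorized; any
    other model is called point by point.
    """
    if getattr(model, "name", "") == "ideal":
        return np.ones((len(xs), 2))
    if isinstance(model, MargulesActivity):
        if model._swapped(comps):
            g = _gamma_grid(
                MargulesActivity(model.a12, model.a21), 1.0 - xs, t, ())
            return g[:, ::-1]
        x1, x2 = xs, 1.0 - xs
        rt = R_GAS * t
        ln_g1 = (model.a12 + 2.0 * (model.a21 - model.a12) * x1) * x2 ** 2 / rt
        ln_g2 = (model.a21 + 2.0 * (model.a12 - model.a21) * x2) * x1 ** 2 / rt
        return np.exp(np.column_stack([ln_g1, ln_g2]))
    return np.array([model.gamma([x, 1.0 - x], t, comps) for x in xs])


def _scan(system: BinarySystem, model, xs: np.ndarray,
          temps: np.ndarray) -> tuple[float, float, float]:
    comps = system.compounds
    best = (np.inf, np.nan, np.nan)
    for t in temps:
        g = _gamma_grid(model, xs, float(t), comps)
        r_i = np.log(xs * g[:, 0]) - _liquidus_rhs(system.comp_i, float(t))
        r_j = np.log((1.0 - xs) * g[:, 1]) - _liquidus_rhs(
            system.comp_j, float(t))
        joint = np.maximum(np.abs(r_i), np.abs(r_j))
        k = int(np.argmin(joint))
        if joint[k] < best[0]:
            best = (float(joint[k]), float(xs[k]), float(t))
    return best


def brute_force_eutectic(
    system: BinarySystem,
    model,
    x_step: float = 1e-4,
    t_step: float = 0.01,
    t_floor: float = 150.0,
) -> EutecticPoint:
    """Grid-scan eutectic oracle, independent of the root-finding solver.

    Minimizes the worse of the two liquidus residuals

        r_i = ln(x g_i) - (dH_i/R)(1/T_fus,i - 1/T)
        r_j = ln((1-x) g_j) - (dH_j/R)(1/T_fus,j - 1/T)

    over a dense (x, T) grid; both residuals vanish only where the two
    branches intersect, which is the eutectic.  The scan is pyramidal for
    tractability: a coarse full-range pass (100x the requested steps) is
    refined at full resolution inside a window of two coarse cells around
    the coarse optimum.  Both joint-residual surfaces are unimodal for
    simple-eutectic systems, so the refinement window always brackets the
    optimum; accuracy is bounded by the requested fine steps.
    """
    if x_step <= 0 or t_step <= 0:
        raise ValueError("grid steps must be positive")
    t_hi = min(system.comp_i.t_fus, system.comp_j.t_fus) - t_step
    if t_hi <= t_floor:
        raise SolverError(f"{system.label}: empty temperature range")
    x_coarse = max(x_step * 100.0, x_step)
    t_coarse = max(t_step * 100.0, t_step)
    joint, x0, t0 = _scan(
        system, model,
        np.arange(x_coarse, 1.0, x_coarse),
        np.arange(t_hi, t_floor, -t_coarse),
    )
    if not np.isfinite(joint):
        raise SolverError(f"{system.label}: no feasible grid point")
    xs = np.arange(max(x0 - 2 * x_coarse, x_step),
                   min(x0 + 2 * x_coarse, 1.0), x_step)
    temps = np.arange(min(t0 + 2 * t_coarse, t_hi),
                      max(t0 - 2 * t_coarse, t_floor), -t_step)
    joint, x_e, t_e = _scan(system, model, xs, temps)
    return EutecticPoint(x_e=x_e, t_e=t_e, model=f"{model.name}-grid",
                         converged=joint < 0.05, residuals=(joint, joint),
                         system=system.label)


def generate_nmr_series(
    slope: float,
    intercept: float,
    temps: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "synthetic",
) -> NMRSeries:
    """Linear-with-noise shift series: delta = intercept + slope*T + eps."""
    temps = [float(t) for t in temps]
    if len(temps) < 3:
        raise ValueError("need at least 3 temperatures")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(temps)) if noise_sd > 0 \
        else np.zeros(len(temps))
    points = tuple((t, intercept + slope * t + float(e))
                   for t, e in zip(temps, noise))
    return NMRSeries(label=label, points=points)
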