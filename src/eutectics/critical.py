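"""Group-contribution critical properties and acentric factor.

Implements the modified Lydersen–Joback–Reid method: the normal boiling
point comes from the Joback–Reid additive scheme, and the critical
temperature, pressure and molar volume from the modified-Lydersen
expressions

    Tb = 198.2 + sum(n_k * dTbM_k)
    Tc = Tb / (0.5703 + 1.0121 * S_T - S_T**2),   S_T = sum(n_k * dTM_k)
    Pc = M / (0.2573 + S_P)**2                    [bar]
    Vc = 6.75 + S_V                               [cm3/mol]

with group constants shipped in ``data/ljr_groups.csv``.  The acentric
factor is not part of the group scheme; it is derived from (Tb, Tc, Pc)
through a vapor-pressure-based correlation — Rudkin's equation by default,
as customarily paired with this method in the deep-eutectic-solvent
property-correlation literature, with Edmister and Lee–Kesler available as
alternatives.  Mixture pseudo-criticals use the Lee–Kesler combining rules
(mole-fraction-linear averaging is available as a simple alternative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .compounds import Compound

#: Gas constant in cm3 bar / (mol K), for the pseudocritical pressure rule.
_R_CM3_BAR = 83.14

#: Normal atmospheric pressure in bar (vapor-pressure anchor point).
_P_ATM_BAR = 1.01325

_METHOD_TB_BASE = 198.2
_METHOD_TC_A = 0.5703
_METHOD_TC_B = 1.0121
_METHOD_PC_C = 0.2573
_METHOD_VC_BASE = 6.75


class GroupTableError(KeyError):
    """A compound uses a group absent from the contribution table."""


class NonPhysicalError(ArithmeticError):
    """An intermediate quantity left its physical domain."""


@dataclass(frozen=True)
class CriticalProps:
    """Critical-point descriptors of a pure compound or a mixture.

    t_c (K), p_c (bar), v_c (cm3/mol), t_b (K), omega (dimensionless).
    ``omega`` is None until an acentric-factor correlation has been applied.
    """

    t_c: float
    p_c: float
    v_c: float
    t_b: float
    omega: float | None = None

    def __post_init__(self) -> None:
        if not (self.t_c > self.t_b > 0):
            raise NonPhysicalError(
                f"require t_c > t_b > 0 (got t_c={self.t_c}, t_b={self.t_b})")
        if self.p_c <= 0 or self.v_c <= 0:
            raise NonPhysicalError("p_c and v_c must be positive")

    def as_dict(self) -> dict:
        return {"Tc_K": self.t_c, "Pc_bar": self.p_c,
                "Vc_cm3_per_mol": self.v_c, "Tb_K": self.t_b,
                "omega": self.omega}


class LJRGroupTable:
    """Contribution table for the modified Lydersen–Joback–Reid method."""

    def __init__(self, frame: pd.DataFrame):
        required = {"group", "dTbM", "dTM", "dPM", "dVM"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"group table missing columns {sorted(missing)}")
        self._rows: dict[str, pd.Series] = {
            row["group"]: row for _, row in frame.iterrows()
        }

    @classmethod
    def from_csv(cls, path: str | Path) -> "LJRGroupTable":
        return cls(pd.read_csv(path, comment="#"))

    @classmethod
    def default(cls) -> "LJRGroupTable":
        return cls.from_csv(Path(__file__).parent / "data" / "ljr_groups.csv")

    def __contains__(self, group: str) -> bool:
        return group in self._rows

    def sum_contributions(self, compound: Compound) -> dict[str, float]:
        """Group-count-weighted sums of the four contribution columns."""
        sums = {"dTbM": 0.0, "dTM": 0.0, "dPM": 0.0, "dVM": 0.0}
        for group, count in compound.ljr_groups.items():
            if group not in self._rows:
                raise GroupTableError(
                    f"group {group!r} of compound {compound.name!r} "
                    f"is not in the contribution table")
            row = self._rows[group]
            for key in sums:
                sums[key] += count * float(row[key])
        return sums


def estimate_boiling_point(compound: Compound, table: LJRGroupTable) -> float:
    """Joback–Reid normal boiling point, K.

    A declared ``t_b`` on the compound takes precedence over estimation.
    """
    if compound.t_b is not None:
        return compound.t_b
    return _METHOD_TB_BASE + table.sum_contributions(compound)["dTbM"]


def estimate_critical_properties(
    compound: Compound, table: LJRGroupTable | None = None
) -> CriticalProps:
    """Tc, Pc, Vc (and Tb) for a pure compound; omega left unset."""
    table = table or LJRGroupTable.default()
    sums = table.sum_contributions(compound)
    t_b = estimate_boiling_point(compound, table)
    s_t, s_p, s_v = sums["dTM"], sums["dPM"], sums["dVM"]
    denom = _METHOD_TC_A + _METHOD_TC_B * s_t - s_t * s_t
    if denom <= 0:
        raise NonPhysicalError(
            f"{compound.name}: Tc denominator {denom:.4g} <= 0 (S_T={s_t:.4g})")
    t_c = t_b / denom
    p_c = compound.mw / (_METHOD_PC_C + s_p) ** 2
    v_c = _METHOD_VC_BASE + s_v
    return CriticalProps(t_c=t_c, p_c=p_c, v_c=v_c, t_b=t_b)


# ---------------------------------------------------------------------------
# Acentric factor
# ---------------------------------------------------------------------------

def _check_omega_inputs(cp: CriticalProps) -> None:
    if not cp.t_b < cp.t_c:
        raise NonPhysicalError("acentric factor needs t_b < t_c")
    if cp.p_c <= 0:
        raise NonPhysicalError("acentric factor needs p_c > 0")


def omega_rudkin(cp: CriticalProps) -> float:
    """Rudkin's acentric-factor equation from (Tb, Tc, Pc).

    omega = [ (Tb-43)(Tc-43) / ((Tc-Tb)(0.7Tc-43)) - (Tc-43)/(Tc-Tb) + 1 ]
            * log10(Pc/Patm) - 1
    """
    _check_omega_inputs(cp)
    t_b, t_c = cp.t_b, cp.t_c
    lg = math.log10(cp.p_c / _P_ATM_BAR)
    bracket = ((t_b - 43.0) * (t_c - 43.0) / ((t_c - t_b) * (0.7 * t_c - 43.0))
               - (t_c - 43.0) / (t_c - t_b) + 1.0)
    return bracket * lg - 1.0


def omega_edmister(cp: CriticalProps) -> float:
    """Edmister correlation: (3/7) * Tbr/(1-Tbr) * log10(Pc/Patm) - 1."""
    _check_omega_inputs(cp)
    tbr = cp.t_b / cp.t_c
    return (3.0 / 7.0) * tbr / (1.0 - tbr) * math.log10(cp.p_c / _P_ATM_BAR) - 1.0


def omega_lee_kesler(cp: CriticalProps) -> float:
    """Lee–Kesler vapor-pressure acentric factor from (Tb, Tc, Pc)."""
    _check_omega_inputs(cp)
    tbr = cp.t_b / cp.t_c
    alpha = (-math.log(cp.p_c / _P_ATM_BAR) - 5.92714 + 6.09648 / tbr
             + 1.28862 * math.log(tbr) - 0.169347 * tbr ** 6)
    beta = (15.2518 - 15.6875 / tbr - 13.4721 * math.log(tbr)
            + 0.43577 * tbr ** 6)
    return alpha / beta


OMEGA_CORRELATIONS = {
    "rudkin": omega_rudkin,
    "edmister": omega_edmister,
    "lee_kesler": omega_lee_kesler,
}


def acentric_factor(cp: CriticalProps, method: str = "rudkin") -> float:
    """Acentric factor via the named correlation (default Rudkin)."""
    try:
        fn = OMEGA_CORRELATIONS[method]
    except KeyError:
        raise ValueError(
            f"unknown omega correlation {method!r}; "
            f"choose from {sorted(OMEGA_CORRELATIONS)}") from None
    return fn(cp)


def with_omega(cp: CriticalProps, method: str = "rudkin") -> CriticalProps:
    """Return a copy of ``cp`` with the acentric factor filled in."""
    return replace(cp, omega=acentric_factor(cp, method))


def compound_critical_properties(
    compound: Compound,
    table: LJRGroupTable | None = None,
    omega_method: str = "rudkin",
) -> CriticalProps:
    """Full pure-component estimate: group sums, then acentric factor."""
    return with_omega(estimate_critical_properties(compound, table),
                      omega_method)


# ---------------------------------------------------------------------------
# Mixture combining rules
# ---------------------------------------------------------------------------

def _check_fractions(fractions: Sequence[float]) -> None:
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"mole fractions sum to {sum(fractions)!r}, not 1")


def mix_lee_kesler(
    components: Sequence[tuple[CriticalProps, float]]
) -> CriticalProps:
    """Lee–Kesler pseudocritical combining rules.

    Vc_ij = ((Vc_i^(1/3) + Vc_j^(1/3)) / 2)^3 ;  Tc_ij = sqrt(Tc_i Tc_j)
    Vc_m  = sum_ij x_i x_j Vc_ij
    Tc_m  = sum_ij x_i x_j Vc_ij Tc_ij / Vc_m
    omega_m = sum_i x_i omega_i
    Pc_m  = (0.2905 - 0.085 omega_m) R Tc_m / Vc_m
    Tb_m  = sum_i x_i Tb_i  (simple average; Tb is not part of the rule set)
    """
    _check_fractions([x for _, x in components])
    v_m = 0.0
    tv_m = 0.0
    for cp_i, x_i in components:
        for cp_j, x_j in components:
            v_ij = ((cp_i.v_c ** (1 / 3) + cp_j.v_c ** (1 / 3)) / 2.0) ** 3
            t_ij = math.sqrt(cp_i.t_c * cp_j.t_c)
            v_m += x_i * x_j * v_ij
            tv_m += x_i * x_j * v_ij * t_ij
    t_c = tv_m / v_m
    omega = sum(x * _require_omega(cp) for cp, x in components)
    p_c = (0.2905 - 0.085 * omega) * _R_CM3_BAR * t_c / v_m
    t_b = sum(x * cp.t_b for cp, x in components)
    return CriticalProps(t_c=t_c, p_c=p_c, v_c=v_m, t_b=t_b, omega=omega)


def mix_linear(
    components: Sequence[tuple[CriticalProps, float]]
) -> CriticalProps:
    """Mole-fraction-weighted averages of every property (Kay-style rule)."""
    _check_fractions([x for _, x in components])
    return CriticalProps(
        t_c=sum(x * cp.t_c for cp, x in components),
        p_c=sum(x * cp.p_c for cp, x in components),
        v_c=sum(x * cp.v_c for cp, x in components),
        t_b=sum(x * cp.t_b for cp, x in components),
        omega=sum(x * _require_omega(cp) for cp, x in components),
    )


def _require_omega(cp: CriticalProps) -> float:
    if cp.omega is None:
        raise ValueError("component CriticalProps lacks an acentric factor")
    return cp.omega


MIXING_RULES = {"lee_kesler": mix_lee_kesler, "linear": mix_linear}


def mix_critical_properties(
    components: Sequence[tuple[CriticalProps, float]],
    rule: str = "lee_kesler",
) -> CriticalProps:
    """Combine pure-component criticals into mixture pseudo-criticals."""
    try:
        fn = MIXING_RULES[rule]
    except KeyError:
        raise ValueError(f"unknown mixing rule {rule!r}; "
                         f"choose from {sorted(MIXING_RULES)}") from None
    return fn(components)


def mixture_critical_properties(
    compounds_and_fractions: Sequence[tuple[Compound, float]],
    table: LJRGroupTable | None = None,
    omega_method: str = "rudkin",
    rule: str = "lee_kesler",
) -> CriticalProps:
    """Pure-component estimation followed by the mixture combining rule."""
    table = table or LJRGroupTable.default()
    comps = [
        (compound_critical_properties(c, table, omega_method), x)
        for c, x in compounds_and_fractions
    ]
    return mix_critical_properties(comps, rule)
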