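"""Activity-coefficient models: ideal solution and original UNIFAC.

UNIFAC splits ln(gamma) into a combinatorial part (molecular size and
shape, Flory–Huggins with the Staverman–Guggenheim correction, z = 10) and
a residual part (group-interaction energies via the solution-of-groups
concept, psi_mn = exp(-a_mn/T)).  Molecules are declared as subgroup count
maps; subgroup R/Q constants and the main-group interaction matrix are
shipped as versioned CSV data files (original VLE parameter set of Hansen
et al. 1991 with the later published revisions).

Both models satisfy the :class:`ActivityModel` contract: ``gamma(x, t,
compounds)`` maps a composition vector summing to one and a temperature to
a strictly positive activity-coefficient vector with gamma_i -> 1 in the
pure-component limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .compounds import Compound

#: Lattice coordination number of the Staverman-Guggenheim term.
Z_COORDINATION = 10.0

#: Data-file version tag recorded in results.
PARAMETER_TABLE_VERSION = "hansen1991-vle-subset-1"


class ActivityModel(Protocol):
    """Contract: composition + temperature -> activity coefficients."""

    name: str

    def gamma(self, x: Sequence[float], t: float,
              compounds: Sequence[Compound]) -> np.ndarray:
        ...


@dataclass(frozen=True)
class IdealSolution:
    """gamma_i = 1 for every component at any state."""

    name: str = "ideal"

    def gamma(self, x: Sequence[float], t: float,
              compounds: Sequence[Compound]) -> np.ndarray:
        _check_composition(x)
        return np.ones(len(x))


def _check_composition(x: Sequence[float]) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or not np.isclose(x.sum(), 1.0, atol=1e-8):
        raise ValueError(f"composition must be a vector summing to 1, got {x}")
    return x


class UNIFACParameterTable:
    """Subgroup R/Q constants plus the main-group interaction matrix."""

    def __init__(self, subgroups: pd.DataFrame, interactions: pd.DataFrame,
                 version: str = PARAMETER_TABLE_VERSION):
        self.version = version
        self._sub: dict[str, tuple[int, float, float]] = {}
        for _, row in subgroups.iterrows():
            if row["R"] <= 0 or row["Q"] < 0:
                raise ValueError(f"bad R/Q for subgroup {row['subgroup']!r}")
            self._sub[row["subgroup"]] = (
                int(row["main_id"]), float(row["R"]), float(row["Q"]))
        self._a: dict[tuple[int, int], float] = {}
        for _, row in interactions.iterrows():
            self._a[(int(row["main_i"]), int(row["main_j"]))] = float(row["a_ij"])

    @classmethod
    def default(cls) -> "UNIFACParameterTable":
        data = Path(__file__).parent / "data"
        return cls(
            pd.read_csv(data / "unifac_subgroups.csv", comment="#"),
            pd.read_csv(data / "unifac_interactions.csv", comment="#"),
        )

    def subgroup(self, name: str) -> tuple[int, float, float]:
        """(main group id, R_k, Q_k) for a subgroup name."""
        try:
            return self._sub[name]
        except KeyError:
            raise KeyError(
                f"subgroup {name!r} not in the parameter table") from None

    def a(self, main_m: int, main_n: int) -> float:
        """Interaction parameter a_mn in K (a_mm = 0)."""
        if main_m == main_n:
            return 0.0
        try:
            return self._a[(main_m, main_n)]
        except KeyError:
            raise KeyError(
                f"no interaction parameter for main-group pair "
                f"({main_m}, {main_n})") from None


def _molecule_groups(compounds: Sequence[Compound],
                     table: UNIFACParameterTable):
    """Assemble the nu matrix, R/Q vectors and main-group ids."""
    subgroup_names: list[str] = []
    for c in compounds:
        if not c.unifac_groups:
            raise ValueError(f"compound {c.name!r} has no UNIFAC groups")
        for g in c.unifac_groups:
            table.subgroup(g)  # raises for uncovered subgroups
            if g not in subgroup_names:
                subgroup_names.append(g)
    n_comp, n_sub = len(compounds), len(subgroup_names)
    nu = np.zeros((n_comp, n_sub))
    for i, c in enumerate(compounds):
        for g, count in c.unifac_groups.items():
            nu[i, subgroup_names.index(g)] = count
    mains = np.array([table.subgroup(g)[0] for g in subgroup_names])
    R = np.array([table.subgroup(g)[1] for g in subgroup_names])
    Q = np.array([table.subgroup(g)[2] for g in subgroup_names])
    return subgroup_names, nu, mains, R, Q


@dataclass(frozen=True)
class UNIFAC:
    """Original UNIFAC with the shipped VLE parameter table."""

    table: UNIFACParameterTable
    name: str = "unifac"

    @classmethod
    def default(cls) -> "UNIFAC":
        return cls(table=UNIFACParameterTable.default())

    # -- combinatorial ----------------------------------------------------

    def ln_gamma_combinatorial(self, x: Sequence[float],
                               compounds: Sequence[Compound]) -> np.ndarray:
        """Flory-Huggins + Staverman-Guggenheim size/shape term.

        r_i = sum_k nu_ik R_k, q_i = sum_k nu_ik Q_k;
        ln gC_i = ln(phi_i/x_i) + (z/2) q_i ln(theta_i/phi_i)
                  + l_i - (phi_i/x_i) sum_j x_j l_j,
        l_i = (z/2)(r_i - q_i) - (r_i - 1).
        """
        x = _check_composition(x)
        _, nu, _, R, Q = _molecule_groups(compounds, self.table)
        r = nu @ R
        q = nu @ Q
        phi_over_x = r / (x @ r)  # phi_i/x_i; finite at x_i = 0
        theta_over_x = q / (x @ q)
        l = Z_COORDINATION / 2.0 * (r - q) - (r - 1.0)
        return (np.log(phi_over_x)
                + Z_COORDINATION / 2.0 * q * np.log(theta_over_x / phi_over_x)
                + l - phi_over_x * (x @ l))

    # -- residual ---------------------------------------------------------

    def _ln_Gamma(self, group_x: np.ndarray, t: float, mains: np.ndarray,
                  Q: np.ndarray) -> np.ndarray:
        """Group activity coefficients ln(Gamma_k) at group fractions X."""
        theta = group_x * Q
        theta = theta / theta.sum()
        psi = np.exp(-np.array([[self.table.a(m, n) for n in mains]
                                for m in mains]) / t)
        s = theta @ psi  # s_n = sum_m theta_m psi_mn
        return Q * (1.0 - np.log(s) - (theta / s) @ psi.T)

    def ln_gamma_residual(self, x: Sequence[float], t: float,
                          compounds: Sequence[Compound]) -> np.ndarray:
        """Solution-of-groups residual term.

        ln gR_i = sum_k nu_ik (ln Gamma_k - ln Gamma_k^(i)), where the
        reference Gamma^(i) is evaluated in pure component i.
        """
        if t <= 0:
            raise ValueError("temperature must be positive")
        x = _check_composition(x)
        _, nu, mains, _, Q = _molecule_groups(compounds, self.table)
        totals = x @ nu
        if totals.sum() <= 0:
            raise ValueError("no groups present at this composition")
        ln_G_mix = self._ln_Gamma(totals / totals.sum(), t, mains, Q)
        out = np.zeros(len(compounds))
        for i in range(len(compounds)):
            pure = nu[i] / nu[i].sum()
            ln_G_pure = self._ln_Gamma(pure, t, mains, Q)
            # subgroups absent from molecule i contribute nothing (nu=0)
            with np.errstate(invalid="ignore"):
                diff = np.where(nu[i] > 0, ln_G_mix - ln_G_pure, 0.0)
            out[i] = nu[i] @ diff
        return out

    def gamma(self, x: Sequence[float], t: float,
              compounds: Sequence[Compound]) -> np.ndarray:
        """gamma_i = exp(ln gC_i + ln gR_i)."""
        return np.exp(self.ln_gamma_combinatorial(x, compounds)
                      + self.ln_gamma_residual(x, t, compounds))


def get_model(name: str,
              table: UNIFACParameterTable | None = None) -> ActivityModel:
    """Model factory used by the CLI (``ideal`` or ``unifac``)."""
    if name == "ideal":
        return IdealSolution()
    if name == "unifac":
        return UNIFAC(table=table or UNIFACParameterTable.default())
    raise ValueError(f"unknown activity model {name!r}")
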