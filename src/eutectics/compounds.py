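"""Compound and binary-system domain types, fixtures and validation.

The unit of every downstream computation is a :class:`Compound`: a named
species with a molecular formula, melting data (fusion temperature and
enthalpy) and two declared group decompositions — one for the UNIFAC
activity model, one for the modified Lydersen–Joback–Reid critical-property
estimation.  Group counts are *data*, not perceived structure; they are
cross-checked against the formula by simple atom balances.

Note on units: enthalpies of fusion are stored in kJ/mol and converted to
J/mol at the point of use in the solid–liquid-equilibrium relation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

#: Universal gas constant, J/(mol K).
R_GAS = 8.314
#: Reference pressure for pressure ratios in the property correlations, bar.
P_REF = 1.0

# Conventional IUPAC atomic weights for formula -> molar mass.
_ATOMIC_WEIGHTS = {
    "H": 1.00794, "C": 12.0107, "N": 14.0067, "O": 15.9994, "F": 18.9984,
    "P": 30.97376, "S": 32.065, "Cl": 35.453, "Br": 79.904, "I": 126.90447,
}

# Atom composition of each UNIFAC subgroup used by the shipped table.
UNIFAC_GROUP_ATOMS: dict[str, dict[str, int]] = {
    "CH3": {"C": 1, "H": 3},
    "CH2": {"C": 1, "H": 2},
    "CH": {"C": 1, "H": 1},
    "C": {"C": 1},
    "ACH": {"C": 1, "H": 1},
    "ACCH3": {"C": 2, "H": 3},
    "ACCH2": {"C": 2, "H": 2},
    "ACCH": {"C": 2, "H": 1},
    "OH": {"O": 1, "H": 1},
    "ACOH": {"C": 1, "O": 1, "H": 1},
    "CH3CO": {"C": 2, "H": 3, "O": 1},
    "CH2CO": {"C": 2, "H": 2, "O": 1},
}

# Atom composition of each Lydersen-Joback-Reid group ("(ring)" marks the
# cyclic-environment variant; atom content is the same as the acyclic one).
LJR_GROUP_ATOMS: dict[str, dict[str, int]] = {
    "CH3": {"C": 1, "H": 3},
    "CH2": {"C": 1, "H": 2},
    "CH": {"C": 1, "H": 1},
    "C": {"C": 1},
    "=CH2": {"C": 1, "H": 2},
    "=CH": {"C": 1, "H": 1},
    "=C": {"C": 1},
    "OH": {"O": 1, "H": 1},
    "O": {"O": 1},
    "C=O": {"C": 1, "O": 1},
    "CHO": {"C": 1, "H": 1, "O": 1},
    "COOH": {"C": 1, "H": 1, "O": 2},
    "CH2(ring)": {"C": 1, "H": 2},
    "CH(ring)": {"C": 1, "H": 1},
    "C(ring)": {"C": 1},
    "=CH(ring)": {"C": 1, "H": 1},
    "=C(ring)": {"C": 1},
    "OH(phenol)": {"O": 1, "H": 1},
    "C=O(ring)": {"C": 1, "O": 1},
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormatError(ValueError):
    """A config file failed to parse or is missing required fields."""


class ValidationError(ValueError):
    """A compound record violates an invariant (e.g. atom balance)."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula such as ``C10H20O``."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormatError(f"cannot parse formula {formula!r} at {pos}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula) or not counts:
        raise FormatError(f"cannot parse formula {formula!r}")
    return counts


def formula_weight(formula: Mapping[str, int]) -> float:
    """Molar mass in g/mol from element counts."""
    try:
        return sum(_ATOMIC_WEIGHTS[el] * n for el, n in formula.items())
    except KeyError as exc:  # pragma: no cover - exotic elements
        raise ValidationError(f"no atomic weight for element {exc}") from exc


@dataclass(frozen=True)
class Compound:
    """A pure species with melting data and group decompositions.

    Parameters
    ----------
    name : str
    formula : mapping of element to count
    mw : molar mass, g/mol
    t_fus : melting temperature, K
    dh_fus : enthalpy of fusion, **kJ/mol**
    unifac_groups : UNIFAC subgroup name -> count (may be empty)
    ljr_groups : Lydersen-Joback-Reid group name -> count (may be empty)
    t_b : normal boiling point, K; None means "estimate when needed"
    """

    name: str
    formula: Mapping[str, int]
    mw: float
    t_fus: float
    dh_fus: float
    unifac_groups: Mapping[str, int] = field(default_factory=dict)
    ljr_groups: Mapping[str, int] = field(default_factory=dict)
    t_b: float | None = None

    def __post_init__(self) -> None:
        for label, value in (("mw", self.mw), ("t_fus", self.t_fus),
                             ("dh_fus", self.dh_fus)):
            if not value > 0:
                raise ValidationError(f"{self.name}: {label} must be > 0")

    @property
    def dh_fus_J(self) -> float:
        """Enthalpy of fusion in J/mol (SLE relation consumes SI units)."""
        return self.dh_fus * 1000.0


@dataclass(frozen=True)
class BinarySystem:
    """Ordered pair of compounds at a preparation mole fraction.

    ``x_i`` always refers to ``comp_i``, the first-listed component of the
    label (e.g. menthol in "Men:Bor").
    """

    comp_i: Compound
    comp_j: Compound
    x_i: float
    label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.x_i <= 1.0:
            raise ValidationError(f"{self.label}: x_i outside [0, 1]")
        if self.comp_i.name == self.comp_j.name:
            raise ValidationError(f"{self.label}: identical components")

    @property
    def x_j(self) -> float:
        return 1.0 - self.x_i

    @property
    def compounds(self) -> tuple[Compound, Compound]:
        return (self.comp_i, self.comp_j)


@dataclass(frozen=True)
class SystemThermalRecord:
    """TGA/DSC observations for a prepared mixture (stored, not computed).

    t_d: degradation temperature; t_cr: crystallization temperature;
    dh_cr: enthalpy of crystallization (J/g); t_g: glass transition (K).
    """

    t_d: float
    t_cr: float
    dh_cr: float
    t_g: float

    def __post_init__(self) -> None:
        if not (0 < self.t_g < self.t_cr < self.t_d):
            raise ValidationError("thermal record requires 0 < t_g < t_cr < t_d")
        if not self.dh_cr > 0:
            raise ValidationError("dh_cr must be > 0")


@dataclass(frozen=True)
class GroupBalanceReport:
    """Per-element residuals (formula minus group-implied atom counts)."""

    compound: str
    residuals: dict[str, dict[str, int]]  # group system -> element -> residual

    @property
    def ok(self) -> bool:
        return all(r == 0 for system in self.residuals.values()
                   for r in system.values())

    def failures(self) -> list[str]:
        return [f"{system}: {el} residual {r:+d}"
                for system, rs in self.residuals.items()
                for el, r in rs.items() if r != 0]


def _implied_atoms(groups: Mapping[str, int],
                   atom_table: Mapping[str, Mapping[str, int]],
                   compound: str) -> dict[str, int]:
    total: dict[str, int] = {}
    for group, count in groups.items():
        try:
            atoms = atom_table[group]
        except KeyError:
            raise ValidationError(
                f"{compound}: unknown group {group!r} in decomposition"
            ) from None
        for el, n in atoms.items():
            total[el] = total.get(el, 0) + n * count
    return total


def validate_group_assignment(compound: Compound) -> GroupBalanceReport:
    """Atom-balance both group decompositions of a compound.

    Each residual is (formula count) − (count implied by summing group
    atom contents); the report passes iff every residual is zero.  Empty
    group maps are skipped (nothing to check).
    """
    residuals: dict[str, dict[str, int]] = {}
    for system, groups, table in (
        ("unifac", compound.unifac_groups, UNIFAC_GROUP_ATOMS),
        ("ljr", compound.ljr_groups, LJR_GROUP_ATOMS),
    ):
        if not groups:
            continue
        implied = _implied_atoms(groups, table, compound.name)
        elements = set(compound.formula) | set(implied)
        residuals[system] = {
            el: compound.formula.get(el, 0) - implied.get(el, 0)
            for el in sorted(elements)
        }
    return GroupBalanceReport(compound=compound.name, residuals=residuals)


# ---------------------------------------------------------------------------
# Config-file I/O
# ---------------------------------------------------------------------------

def _compound_from_record(rec: Mapping, index: int) -> Compound:
    if not isinstance(rec, Mapping):
        raise FormatError(f"compound record {index}: expected a mapping")
    try:
        name = rec["name"]
    except KeyError:
        raise FormatError(f"compound record {index}: missing 'name'") from None
    formula = parse_formula(rec["formula"]) if "formula" in rec else None
    mw = float(rec["mw_g_per_mol"]) if "mw_g_per_mol" in rec else None
    if formula is None and mw is None:
        raise FormatError(f"compound {name!r}: needs 'formula' or 'mw_g_per_mol'")
    if mw is None:
        mw = formula_weight(formula)
    for key in ("t_fus_K", "dh_fus_kJ_per_mol"):
        if key not in rec:
            raise FormatError(f"compound {name!r}: missing {key!r}")
    compound = Compound(
        name=name,
        formula=formula or {},
        mw=mw,
        t_fus=float(rec["t_fus_K"]),
        dh_fus=float(rec["dh_fus_kJ_per_mol"]),
        unifac_groups=dict(rec.get("unifac_groups") or {}),
        ljr_groups=dict(rec.get("ljr_groups") or {}),
        t_b=float(rec["t_b_K"]) if rec.get("t_b_K") is not None else None,
    )
    if formula:
        report = validate_group_assignment(compound)
        if not report.ok:
            raise ValidationError(
                f"compound {name!r}: atom balance failed "
                f"({'; '.join(report.failures())})"
            )
    return compound


def load_compounds(path: str | Path) -> list[Compound]:
    """Load and validate compound records from a YAML config file.

    The file holds either a top-level list of records or a mapping with a
    ``compounds`` key.  Field names carry explicit units (``t_fus_K``,
    ``dh_fus_kJ_per_mol``).  An empty list is valid and returns ``[]``.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: YAML parse failure: {exc}") from exc
    if doc is None:
        return []
    records = doc.get("compounds", []) if isinstance(doc, Mapping) else doc
    if records is None:
        return []
    if not isinstance(records, list):
        raise FormatError(f"{path}: expected a list of compound records")
    return [_compound_from_record(rec, i) for i, rec in enumerate(records)]


def compound_to_record(compound: Compound) -> dict:
    """Serializable record for a compound (inverse of the loader)."""
    rec: dict = {"name": compound.name}
    if compound.formula:
        rec["formula"] = "".join(
            f"{el}{n if n > 1 else ''}"
            for el, n in sorted(
                compound.formula.items(),
                key=lambda kv: {"C": "0", "H": "1"}.get(kv[0], kv[0]),
            )
        )
    rec.update(
        mw_g_per_mol=compound.mw,
        t_fus_K=compound.t_fus,
        dh_fus_kJ_per_mol=compound.dh_fus,
        unifac_groups=dict(compound.unifac_groups),
        ljr_groups=dict(compound.ljr_groups),
    )
    if compound.t_b is not None:
        rec["t_b_K"] = compound.t_b
    return rec


def save_compounds(compounds: Iterable[Compound], path: str | Path) -> None:
    """Write a compound registry back to YAML (round-trips with the loader)."""
    doc = {"compounds": [compound_to_record(c) for c in compounds]}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def export_compounds_csv(compounds: Iterable[Compound],
                         path: str | Path) -> None:
    """Flat CSV export of a registry (group maps serialized as JSON)."""
    import json

    import pandas as pd

    rows = []
    for c in compounds:
        rec = compound_to_record(c)
        for key in ("unifac_groups", "ljr_groups"):
            rec[key] = json.dumps(rec[key], sort_keys=True)
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Built-in fixtures: the four terpenes and four binary systems
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Registry:
    """Immutable bundle of compounds, systems and thermal records."""

    compounds: Mapping[str, Compound]
    systems: Mapping[str, BinarySystem]
    thermal: Mapping[str, SystemThermalRecord]

    def __getitem__(self, key: str) -> BinarySystem:
        return self.systems[key]

    def compound(self, name: str) -> Compound:
        return self.compounds[name]


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def load_registry(path: str | Path) -> Registry:
    """Load a full registry (compounds + systems + thermal records)."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, Mapping):
        raise FormatError(f"{path}: expected a mapping at top level")
    compounds = {c.name: c for c in load_compounds(path)}
    systems: dict[str, BinarySystem] = {}
    for rec in doc.get("systems") or []:
        try:
            comp_i = compounds[rec["comp_i"]]
            comp_j = compounds[rec["comp_j"]]
        except KeyError as exc:
            raise FormatError(f"{path}: system references unknown compound {exc}")
        systems[rec["label"]] = BinarySystem(
            comp_i=comp_i, comp_j=comp_j,
            x_i=float(rec["x_i"]), label=rec["label"],
        )
    thermal = {
        rec["label"]: SystemThermalRecord(
            t_d=float(rec["t_d_K"]), t_cr=float(rec["t_cr_K"]),
            dh_cr=float(rec["dh_cr_J_per_g"]), t_g=float(rec["t_g_K"]),
        )
        for rec in doc.get("thermal_records") or []
    }
    return Registry(compounds=compounds, systems=systems, thermal=thermal)


def builtin_fixtures() -> Registry:
    """The shipped terpene registry: menthol, thymol, borneol, camphor and
    the four binary systems Men:Bor (7:3), Men:Cam (3:2), Thy:Bor (7:3),
    Thy:Cam (1:1), plus the DSC/TGA thermal records of the prepared
    mixtures."""
    return load_registry(_data_path("compounds.yaml"))
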