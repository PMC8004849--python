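"""Report assembly: the full characterization pipeline in one call.

Chains property estimation, SLE phase-diagram computation and
deep-eutectic classification over a registry of binary systems, and
writes tidy CSV/JSON outputs with a provenance block (package version,
parameter-table version, solver tolerances, input checksums, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity import PARAMETER_TABLE_VERSION, get_model
from .compounds import Registry, builtin_fixtures, load_registry
from .properties import property_report
from .sle import RESIDUAL_TOL, T_FLOOR_DEFAULT, SolverError, classify_deep, \
    find_eutectic, phase_diagram


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one characterization run.

    registry_path: compound/system YAML (None -> built-in terpene registry);
    temperature: property-report temperature, K; models: activity models to
    run; outdir: output directory; t_floor: eutectic search floor, K;
    seed: recorded for provenance (the pipeline itself is deterministic).
    """

    registry_path: str | None = None
    temperature: float = 298.0
    models: tuple[str, ...] = ("ideal", "unifac")
    outdir: str = "results"
    t_floor: float = T_FLOOR_DEFAULT
    x_grid_points: int = 99
    seed: int = 0
    grouping: str = "empirical"

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("at least one activity model must be requested")
        if self.t_floor <= 0 or self.x_grid_points < 1:
            raise ValueError("tolerances and grid sizes must be positive")
        if self.registry_path is not None \
                and not Path(self.registry_path).exists():
            raise FileNotFoundError(self.registry_path)


@dataclass
class ReportBundle:
    """In-memory result of a run; ``write`` dumps it to the out directory."""

    properties: pd.DataFrame
    eutectics: pd.DataFrame
    diagrams: pd.DataFrame
    provenance: dict
    failures: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, frame in (("properties.csv", self.properties),
                            ("eutectics.csv", self.eutectics),
                            ("phase_diagrams.csv", self.diagrams)):
            path = outdir / name
            with open(path, "w") as fh:
                fh.write(f"# eutectics {self.provenance['package_version']}; "
                         f"inputs sha256 {self.provenance['input_checksum']}\n")
                frame.to_csv(fh, index=False)
            written.append(path)
        prov = outdir / "provenance.json"
        prov.write_text(json.dumps(self.provenance, indent=2, sort_keys=True))
        written.append(prov)
        return written


def _registry_checksum(registry: Registry) -> str:
    blob = json.dumps(
        {name: (c.mw, c.t_fus, c.dh_fus, sorted(c.unifac_groups.items()),
                sorted(c.ljr_groups.items()))
         for name, c in sorted(registry.compounds.items())},
        sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_characterization(config: RunConfig) -> ReportBundle:
    """Execute the pipeline: properties, eutectics per model, diagrams.

    Solver failures on individual (system, model) pairs are collected in
    ``failures`` rather than aborting the whole run; the CLI maps a
    non-empty failure list to a nonzero exit status.
    """
    registry = (load_registry(config.registry_path)
                if config.registry_path else builtin_fixtures())
    models = {name: get_model(name) for name in config.models}
    prop_rows, eut_rows, diagram_rows, failures = [], [], [], []
    x_grid = np.linspace(0.01, 1.0, config.x_grid_points)
    for label, system in registry.systems.items():
        try:
            prop_rows.append(
                property_report(system, config.temperature,
                                grouping=config.grouping).as_dict())
        except Exception as exc:  # surfaced, not swallowed
            failures.append(f"properties[{label}]: {exc}")
        ideal_t_e = None
        for name, model in models.items():
            try:
                diag = phase_diagram(system, model, x_grid, config.t_floor)
            except SolverError as exc:
                failures.append(f"sle[{label}, {name}]: {exc}")
                continue
            point = diag.eutectic.as_dict()
            if name == "ideal":
                ideal_t_e = diag.eutectic.t_e
            elif ideal_t_e is not None:
                point["classification"] = classify_deep(
                    diag.eutectic.t_e, ideal_t_e)
            eut_rows.append(point)
            diagram_rows.extend(diag.as_rows())
    provenance = {
        "package_version": __version__,
        "unifac_table_version": PARAMETER_TABLE_VERSION,
        "residual_tolerance": RESIDUAL_TOL,
        "t_floor_K": config.t_floor,
        "temperature_K": config.temperature,
        "models": list(config.models),
        "surface_tension_grouping": config.grouping,
        "seed": config.seed,
        "input_checksum": _registry_checksum(registry),
    }
    return ReportBundle(
        properties=pd.DataFrame(prop_rows),
        eutectics=pd.DataFrame(eut_rows),
        diagrams=pd.DataFrame(diagram_rows),
        provenance=provenance,
        failures=failures,
    )
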