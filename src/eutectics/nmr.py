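"""Temperature-coefficient analysis of hydroxyl chemical shifts.

Exchangeable (O-H) protons shift upfield as temperature rises and
hydrogen bonds weaken.  The slope of the chemical shift against
temperature (the temperature coefficient, ppm/K) diagnoses the bonding
regime in nonpolar media: slopes more negative than -0.005 ppm/K indicate
intermolecular hydrogen bonding, slopes less negative than -0.003 ppm/K
intramolecular bonding.  Slopes inside the closed band
[-0.005, -0.003] are reported as indeterminate (the published thresholds
are strict inequalities and leave the band itself unassigned).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy import stats

#: Slope thresholds, ppm/K.
INTERMOLECULAR_THRESHOLD = -0.005
INTRAMOLECULAR_THRESHOLD = -0.003

INTERMOLECULAR = "intermolecular"
INTRAMOLECULAR = "intramolecular"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class NMRSeries:
    """Chemical shift of one proton vs temperature.

    points: ((T in K, delta in ppm), ...) with strictly increasing T and at
    least three entries.
    """

    label: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError(f"{self.label}: need >= 3 points for a fit")
        temps = [t for t, _ in self.points]
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError(
                f"{self.label}: temperatures must be strictly increasing")

    @property
    def temperatures(self) -> list[float]:
        return [t for t, _ in self.points]

    @property
    def shifts(self) -> list[float]:
        return [d for _, d in self.points]


@dataclass(frozen=True)
class TcoeffResult:
    """OLS fit of delta vs T plus the hydrogen-bond classification."""

    label: str
    t_coeff: float  # slope, ppm/K
    intercept: float  # ppm
    r_squared: float
    stderr: float
    classification: str

    def as_dict(self) -> dict:
        return {"series": self.label, "t_coeff_ppm_per_K": self.t_coeff,
                "intercept_ppm": self.intercept, "r_squared": self.r_squared,
                "stderr_ppm_per_K": self.stderr,
                "classification": self.classification}


def classify_hbond(t_coeff: float) -> str:
    """Map a temperature coefficient to a hydrogen-bond regime."""
    if not math.isfinite(t_coeff):
        raise ValueError("temperature coefficient must be finite")
    if t_coeff < INTERMOLECULAR_THRESHOLD:
        return INTERMOLECULAR
    if t_coeff > INTRAMOLECULAR_THRESHOLD:
        return INTRAMOLECULAR
    return INDETERMINATE


def fit_tcoeff(series: NMRSeries) -> TcoeffResult:
    """Ordinary-least-squares temperature coefficient of one series."""
    t, d = series.temperatures, series.shifts
    if max(t) == min(t):
        raise ValueError(f"{series.label}: zero temperature variance")
    fit = stats.linregress(t, d)
    return TcoeffResult(
        label=series.label,
        t_coeff=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        stderr=float(fit.stderr),
        classification=classify_hbond(float(fit.slope)),
    )


def load_series_csv(path: str | Path) -> list[NMRSeries]:
    """Read shift series from CSV with columns T_K, delta_ppm and an
    optional label column (multiple series per file)."""
    frame = pd.read_csv(path, comment="#")
    required = {"T_K", "delta_ppm"}
    if not required <= set(frame.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    out = []
    if "label" in frame.columns:
        groups = frame.groupby("label", sort=False)
    else:
        groups = [(Path(path).stem, frame)]
    for label, g in groups:
        g = g.sort_values("T_K")
        out.append(NMRSeries(
            label=str(label),
            points=tuple(zip(g["T_K"].astype(float),
                             g["delta_ppm"].astype(float)))))
    return out


def analyze_series(series: Sequence[NMRSeries]) -> pd.DataFrame:
    """Fit every series and return a tidy result table."""
    return pd.DataFrame([fit_tcoeff(s).as_dict() for s in series])
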