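"""Quantification and antioxidant-assay statistics.

Covers the rutin calibration line, the total-flavonoid yield formula, and
the three radical-scavenging efficiencies (DPPH, superoxide anion, hydroxyl).
Efficiencies are returned unclamped: values outside [0, 100] signal assay
problems and are flagged, never silently truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParseError, SingularDesignError

__all__ = [
    "StandardCurve",
    "AssayMeasurement",
    "fit_standard_curve",
    "flavonoid_yield",
    "scavenging_dpph",
    "scavenging_superoxide",
    "scavenging_hydroxyl",
    "scavenging",
    "dose_response_curve",
]

ASSAYS = ("dpph", "superoxide", "hydroxyl")


@dataclass
class StandardCurve:
    """Calibration line: absorbance = slope * concentration + intercept."""

    slope: float
    intercept: float
    r2: float

    def absorbance(self, concentration):
        return self.slope * np.asarray(concentration, dtype=float) + self.intercept

    def concentration(self, absorbance):
        """Invert the line: absorbance -> concentration (mg/mL)."""
        return (np.asarray(absorbance, dtype=float) - self.intercept) / self.slope


@dataclass
class AssayMeasurement:
    """One scavenging measurement.

    ``blank`` is the radical-only control (A0/B0, or A_p for hydroxyl),
    ``sample_control`` the radical+sample reading (A1/B1/A_s), and
    ``experimental_control`` the sample-color background (A2/B2/A_b).
    """

    assay: str
    blank: float
    sample_control: float
    experimental_control: float
    concentration: float = float("nan")  # mg/mL

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ParseError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        for name in ("blank", "sample_control", "experimental_control"):
            if getattr(self, name) < 0:
                raise ParseError(f"{name} absorbance must be >= 0")


def fit_standard_curve(concentrations, absorbances) -> StandardCurve:
    """OLS calibration line through (concentration, absorbance) points."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(absorbances, dtype=float)
    if len(x) < 3:
        raise ParseError(f"need at least 3 calibration points, got {len(x)}")
    if np.ptp(x) == 0:
        raise SingularDesignError(["concentration"])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(slope=float(slope), intercept=float(intercept), r2=r2)


def flavonoid_yield(concentration_g_per_ml: float, volume_ml: float, mass_g: float) -> float:
    """Total-flavonoid yield W% = C * V / m * 100."""
    if mass_g <= 0:
        raise ParseError(f"sample mass must be positive, got {mass_g}")
    return concentration_g_per_ml * volume_ml / mass_g * 100.0


def scavenging_dpph(m: AssayMeasurement) -> float:
    """K% = [A0 - (A1 - A2)] / A0 * 100."""
    if m.blank <= 0:
        raise ParseError("blank absorbance must be positive")
    return (m.blank - (m.sample_control - m.experimental_control)) / m.blank * 100.0


def scavenging_superoxide(m: AssayMeasurement) -> float:
    """K% = [B0 - (B1 - B2)] / B0 * 100 (same structure as DPPH)."""
    if m.blank <= 0:
        raise ParseError("blank absorbance must be positive")
    return (m.blank - (m.sample_control - m.experimental_control)) / m.blank * 100.0


def scavenging_hydroxyl(m: AssayMeasurement) -> float:
    """K% = (A_s - A_p) / (A_b - A_p) * 100.

    Note the role of the controls differs from the other two assays; the
    formula is applied exactly as published for this assay's legend.
    """
    denom = m.experimental_control - m.blank
    if denom == 0:
        raise ParseError("hydroxyl assay: A_b must differ from A_p")
    return (m.sample_control - m.blank) / denom * 100.0


_DISPATCH = {
    "dpph": scavenging_dpph,
    "superoxide": scavenging_superoxide,
    "hydroxyl": scavenging_hydroxyl,
}


def scavenging(m: AssayMeasurement) -> float:
    """Dispatch on ``m.assay``."""
    return _DISPATCH[m.assay](m)


def dose_response_curve(measurements) -> pd.DataFrame:
    """Concentration-sorted efficiency table with an out-of-range flag.

    Monotonicity of efficiency in concentration is reported (``monotone``
    column attribute in ``DataFrame.attrs``), not enforced.
    """
    rows = [
        {
            "assay": m.assay,
            "concentration": m.concentration,
            "efficiency": scavenging(m),
        }
        for m in measurements
    ]
    frame = pd.DataFrame(rows).sort_values("concentration", kind="stable")
    frame = frame.reset_index(drop=True)
    frame["out_of_range"] = ~frame["efficiency"].between(0.0, 100.0)
    eff = frame["efficiency"].to_numpy()
    frame.attrs["monotone"] = bool(np.all(np.diff(eff) >= 0))
    return frame
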