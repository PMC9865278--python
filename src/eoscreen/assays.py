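"""Deterministic plate-assay arithmetic for antioxidant and viability endpoints.

Covers the four readout conversions used in essential-oil antioxidant
screening:

* DPPH / ABTS radical scavenging ratio: ``(OD_blank - OD_sample) * 100 / OD_blank``
* FRAP ferric-reducing capacity in Trolox equivalents, via a linear
  calibration ``ΔOD = slope * c + intercept`` with ``ΔOD = OD_sample - OD_blank``
* cellular ROS scavenging percentage from DCFH-DA fluorescence, relative to
  a vehicle control
* CCK-8 viability normalized to vehicle-treated wells

Negative or >100% values are physically meaningful (pro-oxidant behaviour,
proliferation) and are reported with a warning rather than clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    BelowCalibrationWarning,
    DegenerateDesignError,
    InvalidReadingError,
    ProliferationWarning,
    ProOxidantWarning,
)


@dataclass(frozen=True)
class AbsorbanceReading:
    """Blank and sample optical densities from a colorimetric radical assay."""

    od_blank: float
    od_sample: float
    wavelength: float | None = None

    def __post_init__(self) -> None:
        if not self.od_blank > 0:
            raise InvalidReadingError("od_blank must be > 0")
        if self.od_sample < 0:
            raise InvalidReadingError("od_sample must be >= 0")


@dataclass(frozen=True)
class FluorescenceReading:
    """Vehicle and treated fluorescence intensities (DCFH-DA ROS probe)."""

    intensity_vehicle: float
    intensity_treated: float

    def __post_init__(self) -> None:
        if not self.intensity_vehicle > 0:
            raise InvalidReadingError("intensity_vehicle must be > 0")
        if self.intensity_treated < 0:
            raise InvalidReadingError("intensity_treated must be >= 0")


@dataclass(frozen=True)
class LinearCalibration:
    """Straight-line standard curve ``ΔOD = slope * concentration + intercept``."""

    slope: float
    intercept: float
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")

    def forward(self, concentration: float) -> float:
        """Predicted ΔOD at a given concentration (μmol/mL)."""
        return self.slope * np.asarray(concentration, float) + self.intercept


#: The published Trolox standard curve of the rosemary panel's FRAP assay.
TROLOX_CALIBRATION = LinearCalibration(slope=1.2416, intercept=0.0134, r_squared=0.9996)


def radical_scavenging_pct(reading: AbsorbanceReading, background: float = 0.0) -> float:
    """Radical scavenging ratio (%) of a DPPH or ABTS well.

    ``(OD_blank - OD_sample) * 100 / OD_blank`` after optional background
    subtraction.  Negative values (pro-oxidant sample) are returned as-is
    with a :class:`ProOxidantWarning`.
    """
    blank = reading.od_blank - background
    sample = reading.od_sample - background
    if not blank > 0:
        raise InvalidReadingError("background-corrected blank OD must be > 0")
    pct = (blank - sample) * 100.0 / blank
    if pct < 0:
        warnings.warn(
            f"negative scavenging ratio ({pct:.2f}%)", ProOxidantWarning, stacklevel=2
        )
    return pct


def ros_scavenging_pct(reading: FluorescenceReading) -> float:
    """Intracellular ROS reduction (%) relative to the vehicle control."""
    pct = (
        (reading.intensity_vehicle - reading.intensity_treated)
        * 100.0
        / reading.intensity_vehicle
    )
    if pct < 0:
        warnings.warn(
            f"negative ROS reduction ({pct:.2f}%)", ProOxidantWarning, stacklevel=2
        )
    return pct


def viability_pct(od_treated: float, od_vehicle: float) -> float:
    """CCK-8 viability (%) normalized to vehicle-treated wells."""
    if not od_vehicle > 0:
        raise InvalidReadingError("od_vehicle must be > 0")
    if od_treated < 0:
        raise InvalidReadingError("od_treated must be >= 0")
    pct = od_treated * 100.0 / od_vehicle
    if pct > 100:
        warnings.warn(
            f"viability above vehicle ({pct:.2f}%)", ProliferationWarning, stacklevel=2
        )
    return pct


def frap_trolox_equiv(delta_od: float, cal: LinearCalibration = TROLOX_CALIBRATION) -> float:
    """Total antioxidant capacity (μmol Trolox/mL) from a FRAP ΔOD.

    Inverts the standard curve: ``c = (ΔOD - intercept) / slope``.  Values
    below zero are below the calibration range and come back with a
    :class:`BelowCalibrationWarning`.
    """
    conc = (delta_od - cal.intercept) / cal.slope
    if conc < 0:
        warnings.warn(
            f"Trolox equivalent below calibration range ({conc:.4f})",
            BelowCalibrationWarning,
            stacklevel=2,
        )
    return conc


def fit_linear_calibration(
    standards: Sequence[tuple[float, float]]
) -> LinearCalibration:
    """Ordinary least squares fit of (concentration, ΔOD) standard points."""
    if len(standards) < 2:
        raise DegenerateDesignError("need at least two standard points")
    x = np.array([s[0] for s in standards], float)
    y = np.array([s[1] for s in standards], float)
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all standard concentrations identical")
    res = stats.linregress(x, y)
    # rvalue is nan when the responses are exactly constant; the line is flat
    r2 = 1.0 if np.ptp(y) == 0 else float(res.rvalue**2)
    return LinearCalibration(slope=float(res.slope), intercept=float(res.intercept), r_squared=r2)


def aggregate_replicates(values: Sequence[float]) -> tuple[float, float]:
    """Mean ± SD over per-well ratios (mean-of-ratios convention, ddof=1)."""
    arr = np.asarray(list(values), float)
    if arr.size == 0:
        raise ValueError("no replicate values")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


# ---------------------------------------------------------------------------
# Plate-table interface

PLATE_COLUMNS = ("assay", "sample_id", "role", "replicate", "value", "concentration")
ASSAYS = ("DPPH", "ABTS", "FRAP", "ROS", "CCK8")


def read_plate(path) -> pd.DataFrame:
    """Read a plate CSV (assay, sample_id, role, replicate, value[, concentration])."""
    df = pd.read_csv(path)
    missing = {"assay", "sample_id", "role", "replicate", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    return df


def summarize_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-sample mean ± SD endpoint for each assay on a plate table.

    DPPH/ABTS wells are converted against the mean blank OD of the same
    assay; ROS against the mean vehicle intensity; CCK8 against the mean
    vehicle OD; FRAP sample ΔOD (value − mean blank) against the packaged
    Trolox curve unless the plate carries its own ``standard`` rows, in which
    case they are refit.
    """
    out = []
    for assay, sub in plate.groupby("assay"):
        samples = sub[sub["role"] == "sample"]
        if assay in ("DPPH", "ABTS"):
            blank = sub.loc[sub["role"] == "blank", "value"].mean()
            conv = lambda v: radical_scavenging_pct(AbsorbanceReading(blank, v))  # noqa: E731
            unit = "pct"
        elif assay == "ROS":
            veh = sub.loc[sub["role"] == "vehicle", "value"].mean()
            conv = lambda v: ros_scavenging_pct(FluorescenceReading(veh, v))  # noqa: E731
            unit = "pct"
        elif assay == "CCK8":
            veh = sub.loc[sub["role"] == "vehicle", "value"].mean()
            conv = lambda v: viability_pct(v, veh)  # noqa: E731
            unit = "pct"
        elif assay == "FRAP":
            blank = sub.loc[sub["role"] == "blank", "value"].mean()
            std = sub[sub["role"] == "standard"]
            if len(std) >= 2:
                cal = fit_linear_calibration(
                    list(zip(std["concentration"], std["value"] - blank))
                )
            else:
                cal = TROLOX_CALIBRATION
            conv = lambda v: frap_trolox_equiv(v - blank, cal)  # noqa: E731
            unit = "umol_trolox_per_ml"
        else:
            raise ValueError(f"unknown assay {assay!r}")
        for sid, wells in samples.groupby("sample_id"):
            ratios = [conv(v) for v in wells["value"]]
            mean, sd = aggregate_replicates(ratios)
            out.append(
                {
                    "assay": assay,
                    "sample_id": sid,
                    "n": len(ratios),
                    "mean": mean,
                    "sd": sd,
                    "unit": unit,
                }
            )
    return pd.DataFrame(out)
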