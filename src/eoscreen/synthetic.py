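"""Seeded generators for every input the published tables do not include.

Raw instrument and plate readouts of the screening study are not public;
only the per-cultivar mean ± SD composition table and the derived summary
statistics are.  These generators emulate the missing raw layers so the
whole pipeline is exercisable offline:

* replicate composition profiles drawn from the printed means ± SDs
  (truncated-normal draws renormalized to each cultivar's identified total
  — the simplest compositional noise model consistent with mean ± SD
  reporting),
* assay plates (DPPH/ABTS/ROS-style) with configured true scavenging
  ratios,
* dose-response series from a known 4PL truth,
* activity endpoints with a planted single-compound driver,
* random decision matrices, optionally with a dominant alternative.

Every generator takes an integer seed, is bit-reproducible under it, and
records it in the output object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .composition import CompositionTable
from .doseresponse import DoseResponseSeries, four_pl
from .errors import ConfigError, UnknownComponentError
from .topsis import DecisionMatrix

DEFAULT_PLATE_CV = 0.02       # multiplicative well noise of simulated plates
DEFAULT_VIABILITY_SD = 5.0    # additive viability noise, percentage points
#: Cellular ROS reduction panel used in round-trip simulations: the span of
#: reductions the six-cultivar study reports (54.21-86.55%).
ROS_PANEL = {
    "MO": 86.55,
    "DM": 80.0,
    "AL": 73.5,
    "BL": 67.0,
    "MP": 60.5,
    "MJU": 54.21,
}


def _truncated_normal(rng: np.random.Generator, mean, sd) -> np.ndarray:
    """Normal draws truncated at zero by rejection (vectorized)."""
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    out = rng.normal(mean, sd)
    bad = out < 0
    # rejection sampling; the printed SDs are small relative to the means,
    # so a handful of rounds suffices
    while bad.any():
        out[bad] = rng.normal(mean[bad], sd[bad])
        bad = out < 0
    return np.where(sd == 0, mean, out)


def gen_composition_replicates(
    table: CompositionTable, n_rep: int = 3, seed: int = 0
) -> CompositionTable:
    """Replicate composition profiles drawn from a mean ± SD table.

    Per replicate and cultivar, each compound is drawn from a normal
    truncated at zero with the printed mean and SD, then the replicate is
    renormalized to the cultivar's printed identified total (so replicate
    compositions stay compositional).  Absent compounds (mean 0, SD 0) stay
    exactly zero.  ``n_rep=0`` returns the table without replicates.
    """
    if table.sds is None:
        raise ConfigError("table carries no SDs; cannot simulate replicates")
    means = table.means.to_numpy(float)
    sds = table.sds.to_numpy(float)
    if np.any(means < 0) or np.any(sds < 0):
        raise ConfigError("means and SDs must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    totals = table.identified_totals()
    for j, cv in enumerate(table.cultivars):
        for r in range(n_rep):
            draw = _truncated_normal(rng, means[:, j], sds[:, j])
            s = draw.sum()
            if s > 0:
                draw = draw * (totals[cv] / s)
            for name, val in zip(table.compound_names, draw):
                rows.append(
                    {
                        "cultivar": cv,
                        "replicate": r,
                        "compound": name,
                        "area_pct": float(val),
                    }
                )
    reps = pd.DataFrame(rows, columns=["cultivar", "replicate", "compound", "area_pct"])
    return CompositionTable(
        compounds=list(table.compounds),
        means=table.means.copy(),
        sds=table.sds.copy(),
        absent=None if table.absent is None else table.absent.copy(),
        replicates=reps,
        seed=seed,
    )


def gen_dose_response(
    bottom: float,
    top: float,
    ic50: float,
    hill: float,
    conc_levels,
    n_rep: int = 3,
    sd_pct: float = DEFAULT_VIABILITY_SD,
    seed: int = 0,
    sample_id: str = "synthetic",
) -> DoseResponseSeries:
    """Dose-response wells from a known 4PL truth plus Gaussian noise."""
    conc = np.asarray(list(conc_levels), float)
    if np.any(conc <= 0):
        raise ConfigError("concentrations must be strictly positive")
    if sd_pct < 0:
        raise ConfigError("sd_pct must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for c in conc:
        mu = float(four_pl(c, bottom, top, ic50, hill))
        for r in range(n_rep):
            rows.append(
                {
                    "concentration": c,
                    "replicate": r,
                    "viability": mu + (rng.normal(0.0, sd_pct) if sd_pct > 0 else 0.0),
                }
            )
    return DoseResponseSeries(
        data=pd.DataFrame(rows), sample_id=sample_id, seed=seed
    )


def gen_assay_plate(
    true_scavenging_pct: dict[str, float],
    blank_od: float = 0.8,
    cv: float = DEFAULT_PLATE_CV,
    n_rep: int = 3,
    seed: int = 0,
    assay: str = "DPPH",
) -> pd.DataFrame:
    """A plate table whose sample wells encode known true scavenging ratios.

    Sample wells read ``blank_od * (1 - s/100) * (1 + eps)`` with
    ``eps ~ N(0, cv)``; at ``cv=0`` the per-well ratio conversion recovers
    ``s`` exactly.  For ROS-style plates the blank wells play the vehicle
    role (the arithmetic is identical).
    """
    if not blank_od > 0:
        raise ConfigError("blank_od must be > 0")
    for sid, s in true_scavenging_pct.items():
        if not 0 <= s <= 100:
            raise ConfigError(f"true scavenging for {sid!r} outside [0, 100]")
    rng = np.random.default_rng(seed)
    role_blank = "vehicle" if assay in ("ROS", "CCK8") else "blank"
    rows = [
        {
            "assay": assay,
            "sample_id": "blank",
            "role": role_blank,
            "replicate": r,
            "value": blank_od,
            "concentration": np.nan,
        }
        for r in range(n_rep)
    ]
    for sid, s in true_scavenging_pct.items():
        base = blank_od * (1.0 - s / 100.0)
        for r in range(n_rep):
            eps = rng.normal(0.0, cv) if cv > 0 else 0.0
            rows.append(
                {
                    "assay": assay,
                    "sample_id": sid,
                    "role": "sample",
                    "replicate": r,
                    "value": base * (1.0 + eps),
                    "concentration": np.nan,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["seed"] = seed
    return out


def gen_planted_activity(
    composition: CompositionTable,
    driver: str,
    slope: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    endpoint: str = "activity",
    level: str = "auto",
) -> pd.DataFrame:
    """Activity endpoint driven linearly by one compound's percentage.

    ``endpoint = slope * driver% + N(0, noise_sd)`` per sample.  Samples are
    replicate profiles when the table has them (``level="auto"``), else the
    cultivar means.  At ``noise_sd=0`` the Spearman correlation between the
    driver and the endpoint is exactly ±1 (sign of ``slope``).
    """
    driver_row = composition.record(driver).name  # raises UnknownComponentError
    rng = np.random.default_rng(seed)
    if composition.replicates is not None and level in ("auto", "replicate"):
        x, _ = composition.replicate_matrix()
        idx = ["{}::{}".format(c, r) for c, r in x.index]
        drv = x[driver_row].to_numpy(float)
    else:
        drv = composition.means.loc[driver_row].to_numpy(float)
        idx = composition.cultivars
    vals = slope * drv + (rng.normal(0.0, noise_sd, len(drv)) if noise_sd > 0 else 0.0)
    out = pd.DataFrame({endpoint: vals}, index=pd.Index(idx, name="sample"))
    out.attrs["seed"] = seed
    out.attrs["driver"] = driver_row
    return out


def gen_decision_matrix(
    m: int,
    n: int,
    dominant: int | None = None,
    seed: int = 0,
    low: float = 1.0,
    high: float = 10.0,
) -> DecisionMatrix:
    """Random positive decision matrix, optionally with a dominant alternative.

    With ``dominant=i``, row i is lifted strictly above the column-wise
    maximum of the other rows in every criterion, so TOPSIS must give it
    closeness 1 and rank 1.
    """
    if m < 2 or n < 1:
        raise ConfigError("need m >= 2 alternatives and n >= 1 criteria")
    rng = np.random.default_rng(seed)
    vals = rng.uniform(low, high, size=(m, n))
    if dominant is not None:
        others = np.delete(vals, dominant, axis=0)
        vals[dominant] = others.max(axis=0) * 1.25
    df = pd.DataFrame(
        vals,
        index=[f"A{i}" for i in range(m)],
        columns=[f"C{j}" for j in range(n)],
    )
    return DecisionMatrix(values=df, directions=["benefit"] * n, seed=seed)


def gen_frap_plate(
    true_trolox_umol_ml: dict[str, float],
    blank_od: float = 0.2,
    cv: float = DEFAULT_PLATE_CV,
    n_rep: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """A FRAP plate whose sample wells encode known Trolox equivalents.

    Sample wells read ``blank + (slope*c + intercept)*(1 + eps)`` using the
    packaged Trolox calibration, so inverting the line on ΔOD recovers the
    configured concentration (exactly at ``cv=0``).
    """
    from .assays import TROLOX_CALIBRATION

    rng = np.random.default_rng(seed)
    rows = [
        {
            "assay": "FRAP",
            "sample_id": "blank",
            "role": "blank",
            "replicate": r,
            "value": blank_od,
            "concentration": np.nan,
        }
        for r in range(n_rep)
    ]
    for sid, c in true_trolox_umol_ml.items():
        if c < 0:
            raise ConfigError(f"Trolox equivalent for {sid!r} must be >= 0")
        delta = float(TROLOX_CALIBRATION.forward(c))
        for r in range(n_rep):
            eps = rng.normal(0.0, cv) if cv > 0 else 0.0
            rows.append(
                {
                    "assay": "FRAP",
                    "sample_id": sid,
                    "role": "sample",
                    "replicate": r,
                    "value": blank_od + delta * (1.0 + eps),
                    "concentration": np.nan,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["seed"] = seed
    return out


def gen_antioxidant_panel(
    cultivars=("MJU", "DM", "AL", "MP", "MO", "BL"),
    seed: int = 0,
    cv: float = DEFAULT_PLATE_CV,
    n_rep: int = 3,
    dominant: str | None = None,
) -> pd.DataFrame:
    """Four-assay plate bundle (DPPH, ABTS, FRAP, ROS) for a cultivar panel.

    Scavenging-type truths are drawn uniformly in [40, 90] %, FRAP truths in
    [0.4, 1.5] μmol Trolox/mL; with ``dominant`` set, that cultivar gets the
    highest true value in every assay.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for k, assay in enumerate(("DPPH", "ABTS", "ROS")):
        truths = dict(zip(cultivars, rng.uniform(40.0, 90.0, len(cultivars))))
        if dominant is not None:
            truths[dominant] = min(max(truths.values()) + 5.0, 99.0)
        frames.append(
            gen_assay_plate(
                truths, cv=cv, n_rep=n_rep, seed=seed * 7919 + k, assay=assay
            )
        )
    frap_truths = dict(zip(cultivars, rng.uniform(0.4, 1.5, len(cultivars))))
    if dominant is not None:
        frap_truths[dominant] = max(frap_truths.values()) * 1.1
    frames.append(
        gen_frap_plate(frap_truths, cv=cv, n_rep=n_rep, seed=seed * 7919 + 3)
    )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["seed"] = seed
    return out
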