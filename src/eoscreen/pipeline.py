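"""Config-driven orchestration of the screening analysis chain.

Reproduces the study design end-to-end: summarize assay plates into a
cultivar × {DPPH, ABTS, FRAP, ROS} decision matrix, rank overall antioxidant
capacity with TOPSIS, regress the closeness coefficient on composition with
a node-purity random forest, and correlate composition with activity
endpoints (Spearman).  Every run records its seeds and configuration and
writes deterministic tabular reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assays, chemometrics, composition as comp, topsis as tp
from .errors import ConfigError

#: Assay endpoints that form the antioxidant decision matrix, in column order.
ANTIOXIDANT_CRITERIA = ("DPPH", "ABTS", "FRAP", "ROS")


@dataclass
class RunConfig:
    """Validated run configuration (YAML-loadable; unknown keys rejected)."""

    directions: list[str] | str = "benefit"
    weights: list[float] | None = None
    cineole_threshold: float = 20.0
    scaling: str = "pareto"
    n_orth: int = 1
    n_trees: int = 500
    seed: int = 0
    ic50_mode: str = "absolute"
    multiple_testing: str | None = None  # None (raw p, the study convention) or "bh"
    rf_level: str = "auto"  # regress Ci on replicates when available, else means
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        """Stable hash of the configuration for run logs."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def build_decision_matrix(
    assay_summary: pd.DataFrame,
    cultivars: list[str],
    directions=None,
    weights=None,
) -> tp.DecisionMatrix:
    """Cultivar × criterion decision matrix from a summarized assay table.

    ``assay_summary`` is the output of :func:`eoscreen.assays.summarize_plate`
    (columns assay, sample_id, mean).  Every cultivar must carry every
    criterion endpoint.
    """
    wide = assay_summary.pivot_table(index="sample_id", columns="assay", values="mean")
    missing_cols = [a for a in ANTIOXIDANT_CRITERIA if a not in wide.columns]
    if missing_cols:
        raise ConfigError(f"assay table lacks criteria: {missing_cols}")
    wide = wide.reindex(index=cultivars, columns=list(ANTIOXIDANT_CRITERIA))
    if wide.isna().any().any():
        bad = sorted(wide.index[wide.isna().any(axis=1)])
        raise ConfigError(f"incomplete criteria for cultivar(s): {bad}")
    dirs = (
        [directions] * wide.shape[1]
        if directions is None or isinstance(directions, str)
        else list(directions)
    )
    if directions is None:
        dirs = ["benefit"] * wide.shape[1]
    return tp.DecisionMatrix(values=wide, directions=dirs, weights=weights)


def run_antioxidant_evaluation(
    assay_table: pd.DataFrame,
    composition_table: comp.CompositionTable,
    config: RunConfig | None = None,
) -> dict:
    """TOPSIS ranking of overall antioxidant capacity + RF component screen.

    ``assay_table`` is a raw plate table (converted via
    :func:`~eoscreen.assays.summarize_plate`) or an already-summarized table
    with columns ``assay, sample_id, mean``.  Returns a report bundle with
    the decision matrix, the Table-style ranking frame, the node-purity
    importances and a JSON-serializable summary.
    """
    config = config or RunConfig()
    if "role" in assay_table.columns:
        summary = assays.summarize_plate(assay_table)
    else:
        summary = assay_table
    dm = build_decision_matrix(
        summary,
        composition_table.cultivars,
        directions=config.directions,
        weights=config.weights,
    )
    result = tp.topsis(dm)

    if composition_table.replicates is not None and config.rf_level in ("auto", "replicate"):
        x, labels = composition_table.replicate_matrix()
        y = result.closeness.reindex(labels.to_numpy()).to_numpy()
        x = x.reset_index(drop=True)
    else:
        x = composition_table.means.T
        y = result.closeness.reindex(x.index).to_numpy()
    imp = chemometrics.rf_regression_importance(
        x, y, n_trees=config.n_trees, seed=config.seed
    )
    return {
        "decision_matrix": dm.values,
        "topsis": result.to_frame(),
        "topsis_result": result,
        "importance": imp.importances.sort_values(ascending=False),
        "summary": {
            "config": config.digest(),
            "seed": config.seed,
            "n_trees": imp.n_trees,
            "oob_mse": imp.oob_mse,
            "best": str(result.closeness.idxmax()),
            "top_component": str(imp.importances.idxmax()),
        },
    }


def benjamini_hochberg(p: pd.DataFrame) -> pd.DataFrame:
    """BH-adjusted p-values, applied per endpoint column (NaNs passed through)."""
    out = p.copy()
    for col in out.columns:
        vals = out[col].to_numpy(float)
        ok = np.isfinite(vals)
        m = ok.sum()
        if m == 0:
            continue
        order = np.argsort(vals[ok])
        ranked = vals[ok][order] * m / (np.arange(m) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        tmp = np.full(m, np.nan)
        tmp[order] = np.minimum(adj, 1.0)
        vals[ok] = tmp
        out[col] = vals
    return out


def run_composition_activity(
    composition_table: comp.CompositionTable,
    activity: pd.DataFrame,
    config: RunConfig | None = None,
) -> dict:
    """Spearman correlation report of compound % against activity endpoints.

    ``activity`` is a samples × endpoints frame (index: cultivar or
    replicate labels matching the composition samples).  An empty endpoint
    list yields an empty report.
    """
    config = config or RunConfig()
    if activity.shape[1] == 0:
        empty = pd.DataFrame(index=composition_table.compound_names)
        return {"rho": empty, "p": empty, "stars": empty, "summary": {}}
    x = composition_table.means.T  # cultivar × compound
    shared = x.index.intersection(activity.index)
    if composition_table.replicates is not None and len(shared) < 3:
        xr, _ = composition_table.replicate_matrix()
        xr.index = ["{}::{}".format(c, r) for c, r in xr.index]
        x = xr
        shared = x.index.intersection(activity.index)
    res = chemometrics.spearman_matrix(x.loc[shared], activity.loc[shared])
    p = res.p
    if config.multiple_testing == "bh":
        p = benjamini_hochberg(p)
    stars = p.map(chemometrics.significance_stars)
    best = res.strongest_pair()
    return {
        "rho": res.rho,
        "p": p,
        "stars": stars,
        "n": res.n,
        "summary": {
            "config": config.digest(),
            "strongest_component": best[0],
            "strongest_endpoint": best[1],
            "strongest_rho": best[2],
            "multiple_testing": config.multiple_testing,
        },
    }


def write_correlation_tsv(report: dict, path) -> None:
    """Long-form correlation TSV: component, endpoint, rho, p, stars."""
    rows = []
    for comp_name in report["rho"].index:
        for ep in report["rho"].columns:
            rows.append(
                {
                    "component": comp_name,
                    "endpoint": ep,
                    "rho": round(float(report["rho"].loc[comp_name, ep]), 4)
                    if np.isfinite(report["rho"].loc[comp_name, ep])
                    else "",
                    "p": round(float(report["p"].loc[comp_name, ep]), 6)
                    if np.isfinite(report["p"].loc[comp_name, ep])
                    else "",
                    "stars": report["stars"].loc[comp_name, ep],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_bundle(report: dict, out_dir, prefix: str = "antioxidant") -> list[Path]:
    """Write an antioxidant-evaluation report bundle; returns written paths.

    Ci/Di are rounded to 4 decimals in the TSV (table convention); full
    precision goes to the sidecar JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    tsv = out / f"{prefix}_topsis.tsv"
    tp.write_result_tsv(report["topsis_result"], tsv)
    written.append(tsv)
    imp = out / f"{prefix}_importance.tsv"
    report["importance"].round(6).to_csv(imp, sep="\t", header=["inc_node_purity"])
    written.append(imp)
    side = out / f"{prefix}_summary.json"
    payload = dict(report["summary"])
    payload["closeness_full_precision"] = {
        str(k): float(v) for k, v in report["topsis_result"].closeness.items()
    }
    side.write_text(json.dumps(payload, indent=2, sort_keys=True))
    written.append(side)
    return written
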