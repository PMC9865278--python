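"""GC-MS relative-composition tables for essential-oil panels.

The composition unit throughout is the relative peak-area percent: a
compound's GC peak area as a percentage of the total integrated area of the
chromatogram.  A panel is a cultivar × compound matrix of such percentages,
reported as mean ± SD over replicate injections.  This module models those
tables, computes retention indices against an n-alkane ladder, aggregates
class totals, extracts main-component mass fractions and assigns chemotype
labels (the within-species chemical variants named after a dominant
component, e.g. "α-pinene-type").
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AnnotationError,
    OutOfRangeError,
    UnknownComponentError,
)

COMPOUND_CLASSES = (
    "monoterpene_hydrocarbon",
    "monoterpene_alcohol",
    "monoterpene_ketone",
    "monoterpene_ether",
    "monoterpene_ester",
    "sesquiterpene",
    "miscellaneous",
)

#: Classes whose members are oxygenated monoterpenes by construction.
_OXY_MONOTERPENE_CLASSES = frozenset(
    {
        "monoterpene_alcohol",
        "monoterpene_ketone",
        "monoterpene_ether",
        "monoterpene_ester",
    }
)

#: Fixed cultivar label set of the packaged rosemary panel.
ROSEMARY_CULTIVARS = ("MJU", "DM", "AL", "MP", "MO", "BL")


def normalize_name(name: str) -> str:
    """Canonical form of a compound name for lookups (NFC, casefolded, trimmed)."""
    return unicodedata.normalize("NFC", name).strip().casefold()


@dataclass(frozen=True)
class CompoundRecord:
    """Identification metadata for one compound in a composition table.

    ``oxygenated`` records whether the molecule bears oxygen; it matters only
    for sesquiterpenes, where the printed summary convention pools oxygenated
    sesquiterpenoids with the oxygenated monoterpenes.
    """

    name: str
    compound_class: str
    ri_calculated: float | None = None
    ri_reference: float | None = None
    evidence: frozenset[str] = field(default_factory=frozenset)
    oxygenated: bool | None = None

    def __post_init__(self) -> None:
        if self.compound_class not in COMPOUND_CLASSES:
            raise AnnotationError(
                f"compound {self.name!r} has unknown class {self.compound_class!r}"
            )
        if self.ri_calculated is not None and not self.ri_calculated > 0:
            raise ValueError(f"compound {self.name!r}: ri_calculated must be > 0")

    @property
    def is_oxygenated(self) -> bool:
        if self.oxygenated is not None:
            return self.oxygenated
        return self.compound_class in _OXY_MONOTERPENE_CLASSES


@dataclass
class CompositionTable:
    """Cultivar × compound table of relative peak-area percentages.

    ``means``/``sds`` are compound × cultivar DataFrames (mean and SD over
    replicate determinations); ``absent`` flags entries printed as "-" (not
    detected), which are stored as true zeros.  ``replicates`` optionally
    holds per-replicate draws in long form (columns ``cultivar``,
    ``replicate``, ``compound``, ``area_pct``).
    """

    compounds: list[CompoundRecord]
    means: pd.DataFrame
    sds: pd.DataFrame | None = None
    absent: pd.DataFrame | None = None
    replicates: pd.DataFrame | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.compounds]
        if list(self.means.index) != names:
            raise ValueError("means index must match compound records in order")
        vals = self.means.to_numpy(float)
        if np.any(vals < 0) or np.any(vals > 100):
            raise ValueError("relative-area percentages must lie in [0, 100]")
        totals = vals.sum(axis=0)
        if np.any(totals <= 0) or np.any(totals > 100.5):
            raise ValueError(
                "per-cultivar identified totals must lie in (0, 100.5]"
            )
        if self.absent is None:
            self.absent = self.means == 0.0
        self._by_name = {normalize_name(c.name): c for c in self.compounds}

    @property
    def cultivars(self) -> list[str]:
        return list(self.means.columns)

    @property
    def compound_names(self) -> list[str]:
        return list(self.means.index)

    def record(self, name: str) -> CompoundRecord:
        key = normalize_name(name)
        if key not in self._by_name:
            raise UnknownComponentError(name)
        return self._by_name[key]

    def profile(self, cultivar: str) -> pd.Series:
        """Mean composition profile (compound -> %) of one cultivar."""
        if cultivar not in self.means.columns:
            raise KeyError(cultivar)
        return self.means[cultivar]

    def identified_totals(self) -> pd.Series:
        """Sum of identified relative-area % per cultivar."""
        return self.means.sum(axis=0)

    def resolve(self, names: Iterable[str]) -> list[str]:
        """Map user-supplied names onto table row labels (case-insensitive)."""
        return [self.record(n).name for n in names]

    def replicate_matrix(self) -> tuple[pd.DataFrame, pd.Series]:
        """Pivot replicates into a samples × compounds matrix plus cultivar labels."""
        if self.replicates is None:
            raise ValueError("table has no replicate-level data")
        wide = self.replicates.pivot_table(
            index=["cultivar", "replicate"], columns="compound", values="area_pct"
        ).fillna(0.0)
        wide = wide.reindex(columns=self.compound_names).fillna(0.0)
        labels = wide.index.get_level_values("cultivar").to_series(index=wide.index)
        return wide, labels


@dataclass(frozen=True)
class AlkaneLadder:
    """Retention times (min) of an n-alkane homologous series (C7–C40)."""

    entries: Mapping[int, float]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise ValueError("ladder needs at least two alkanes")
        ns = sorted(self.entries)
        rts = [self.entries[n] for n in ns]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("retention times must increase strictly with carbon number")
        object.__setattr__(self, "_ns", ns)
        object.__setattr__(self, "_rts", rts)

    @property
    def span(self) -> tuple[float, float]:
        return self._rts[0], self._rts[-1]


def compute_retention_index(rt: float, ladder: AlkaneLadder) -> float:
    """Retention index of a peak by linear interpolation in the alkane ladder.

    Uses the temperature-programmed (van den Dool–Kratz) form
    ``RI = 100 * (n + (rt - rt_n) / (rt_{n+1} - rt_n))`` where the peak elutes
    between the C_n and C_{n+1} alkanes.  No extrapolation outside the ladder.
    """
    lo, hi = ladder.span
    if rt < lo or rt > hi:
        raise OutOfRangeError(
            f"retention time {rt} min outside ladder span [{lo}, {hi}] min"
        )
    ns, rts = ladder._ns, ladder._rts
    k = int(np.searchsorted(rts, rt, side="right")) - 1
    k = min(max(k, 0), len(ns) - 2)
    n, n_next = ns[k], ns[k + 1]
    frac = (rt - rts[k]) / (rts[k + 1] - rts[k])
    # non-consecutive ladder entries interpolate across the carbon-number gap
    return 100.0 * (n + frac * (n_next - n))


def match_reference(
    ri: float,
    library: Sequence[tuple[str, float]],
    tol: float,
) -> list[tuple[str, float]]:
    """Library entries within ``tol`` RI units, nearest first (ties alphabetical)."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    hits = [(name, ref) for name, ref in library if abs(ri - ref) <= tol]
    return sorted(hits, key=lambda e: (abs(ri - e[1]), e[0]))


def class_sums(table: CompositionTable) -> pd.DataFrame:
    """Per-cultivar totals of mean relative-area % by compound class.

    Absent compounds contribute zero.  Result is class × cultivar, including
    classes absent from the table (as zero rows).
    """
    if not table.compounds:
        return pd.DataFrame(index=pd.Index(COMPOUND_CLASSES, name="compound_class"))
    classes = pd.Series(
        [c.compound_class for c in table.compounds], index=table.means.index
    )
    out = table.means.groupby(classes).sum()
    out = out.reindex(COMPOUND_CLASSES).fillna(0.0)
    out.index.name = "compound_class"
    return out


#: Printed summary-row groups.  Oxygenated sesquiterpenoids are pooled with
#: the oxygenated monoterpenes and only sesquiterpene hydrocarbons remain in
#: the sesquiterpene row — the pooling the published class-total rows use.
SUMMARY_GROUPS = (
    "monoterpene_hydrocarbons",
    "oxygenated_monoterpenes",
    "sesquiterpenes",
    "others",
)


def _summary_group(rec: CompoundRecord) -> str:
    if rec.compound_class == "monoterpene_hydrocarbon":
        return "monoterpene_hydrocarbons"
    if rec.compound_class in _OXY_MONOTERPENE_CLASSES:
        return "oxygenated_monoterpenes"
    if rec.compound_class == "sesquiterpene":
        return "oxygenated_monoterpenes" if rec.is_oxygenated else "sesquiterpenes"
    return "others"


def summary_rows(table: CompositionTable) -> pd.DataFrame:
    """Recompute the published class-total rows (group × cultivar)."""
    if not table.compounds:
        return pd.DataFrame(index=pd.Index(SUMMARY_GROUPS, name="group"))
    groups = pd.Series(
        [_summary_group(c) for c in table.compounds], index=table.means.index
    )
    out = table.means.groupby(groups).sum()
    out = out.reindex(SUMMARY_GROUPS).fillna(0.0)
    out.index.name = "group"
    return out


#: Chemotype rules: (label, component, threshold %).  The cineole threshold
#: has no published value and is configurable.
CHEMOTYPE_RULES = (
    ("α-pinene-type", "α-pinene", 20.0),
    ("camphor-type", "camphor", 20.0),
    ("verbenone-type", "verbenone", 15.0),
)
_CINEOLE = "1,8-cineole"


def classify_chemotype(
    profile: Mapping[str, float],
    cineole_threshold: float = 20.0,
) -> list[str]:
    """Chemotype labels whose rule fires, ordered by the triggering %.

    Rules: α-pinene-type (α-pinene > 20%), camphor-type (camphor > 20%),
    verbenone-type (verbenone > 15%), cineole-type (1,8-cineole above the
    configured threshold).  The cineole label is suppressed when another
    rule component exceeds the cineole percentage, so oils dominated by a
    different component keep a single unambiguous call.
    """
    prof = {normalize_name(k): float(v) for k, v in profile.items()}
    for v in prof.values():
        if v < 0 or v > 100:
            raise ValueError("profile percentages must lie in [0, 100]")

    fired: list[tuple[str, float]] = []
    for label, comp, thresh in CHEMOTYPE_RULES:
        pct = prof.get(normalize_name(comp), 0.0)
        if pct > thresh:
            fired.append((label, pct))
    cineole_pct = prof.get(normalize_name(_CINEOLE), 0.0)
    if cineole_pct > cineole_threshold:
        others = [
            prof.get(normalize_name(comp), 0.0) for _, comp, _ in CHEMOTYPE_RULES
        ]
        if not any(o > cineole_pct for o in others):
            fired.append(("1,8-cineole-type", cineole_pct))
    fired.sort(key=lambda t: -t[1])
    return [label for label, _ in fired]


def chemotype_table(
    table: CompositionTable, cineole_threshold: float = 20.0
) -> dict[str, list[str]]:
    """Chemotype calls for every cultivar in a composition table."""
    return {
        cv: classify_chemotype(table.profile(cv).to_dict(), cineole_threshold)
        for cv in table.cultivars
    }


def main_components_fraction(
    table: CompositionTable, components: Sequence[str]
) -> tuple[pd.Series, float, float]:
    """Summed mean % of the named components per cultivar, plus min/max.

    Raises :class:`UnknownComponentError` for a name absent from the table;
    components undetected in a particular cultivar contribute zero there.
    """
    if not components:
        raise ValueError("components must be non-empty")
    rows = table.resolve(components)
    sums = table.means.loc[rows].sum(axis=0)
    return sums, float(sums.min()), float(sums.max())


# ---------------------------------------------------------------------------
# I/O

_MEAN_SD = re.compile(
    r"^\s*(?P<mean>\d+(?:\.\d+)?)\s*(?:±|\+/-)\s*(?P<sd>\d+(?:\.\d+)?)\s*$"
)


def _parse_cell(cell: str) -> tuple[float, float, bool]:
    """Parse a wide-table cell: 'mean ± sd', a bare number, or '-' (absent)."""
    s = str(cell).strip()
    if s in {"-", "", "nan"}:
        return 0.0, 0.0, True
    m = _MEAN_SD.match(s)
    if m:
        return float(m.group("mean")), float(m.group("sd")), False
    return float(s), 0.0, False


def read_composition_wide(path) -> CompositionTable:
    """Read a wide-form composition CSV (compounds × cultivars, 'mean ± sd' cells).

    Expected columns: ``compound``, ``compound_class``, optional ``oxygenated``
    / ``ri_calculated`` / ``ri_reference`` / ``evidence`` / ``no``, then one
    column per cultivar.
    """
    raw = pd.read_csv(path, dtype=str)
    meta_cols = {
        "no",
        "compound",
        "compound_class",
        "oxygenated",
        "ri_calculated",
        "ri_reference",
        "evidence",
    }
    cultivars = [c for c in raw.columns if c not in meta_cols]
    records: list[CompoundRecord] = []
    means = np.zeros((len(raw), len(cultivars)))
    sds = np.zeros_like(means)
    absent = np.zeros(means.shape, dtype=bool)
    for i, row in raw.iterrows():
        oxy = row.get("oxygenated")
        records.append(
            CompoundRecord(
                name=row["compound"],
                compound_class=row["compound_class"],
                ri_calculated=(
                    float(row["ri_calculated"])
                    if pd.notna(row.get("ri_calculated"))
                    else None
                ),
                ri_reference=(
                    float(row["ri_reference"])
                    if pd.notna(row.get("ri_reference"))
                    else None
                ),
                evidence=frozenset(
                    str(row.get("evidence", "")).replace(" ", "").split(",")
                )
                - {""},
                oxygenated=(
                    None if pd.isna(oxy) else str(oxy).strip().lower() in {"yes", "true", "1"}
                ),
            )
        )
        for j, cv in enumerate(cultivars):
            means[i, j], sds[i, j], absent[i, j] = _parse_cell(row[cv])
    names = [r.name for r in records]
    return CompositionTable(
        compounds=records,
        means=pd.DataFrame(means, index=names, columns=cultivars),
        sds=pd.DataFrame(sds, index=names, columns=cultivars),
        absent=pd.DataFrame(absent, index=names, columns=cultivars),
    )


def read_composition_long(path) -> CompositionTable:
    """Read a long-form composition CSV.

    Columns: ``cultivar``, optional ``replicate``, ``compound``,
    ``compound_class``, optional ``ri_calculated``/``ri_reference``/
    ``evidence``, ``area_pct``.  With a ``replicate`` column, means and SDs
    are aggregated over replicates and the replicate level is retained.
    """
    df = pd.read_csv(path)
    has_rep = "replicate" in df.columns and df["replicate"].notna().any()
    recs: dict[str, CompoundRecord] = {}
    for _, row in df.drop_duplicates("compound").iterrows():
        recs[row["compound"]] = CompoundRecord(
            name=row["compound"],
            compound_class=row["compound_class"],
            ri_calculated=(
                float(row["ri_calculated"])
                if "ri_calculated" in df.columns and pd.notna(row["ri_calculated"])
                else None
            ),
            ri_reference=(
                float(row["ri_reference"])
                if "ri_reference" in df.columns and pd.notna(row["ri_reference"])
                else None
            ),
            evidence=frozenset(
                str(row["evidence"]).replace(" ", "").split(",")
            )
            - {"", "nan"}
            if "evidence" in df.columns
            else frozenset(),
        )
    cultivars = list(dict.fromkeys(df["cultivar"]))
    names = list(recs)
    if has_rep:
        piv = df.pivot_table(
            index="compound", columns="cultivar", values="area_pct", aggfunc="mean"
        )
        sd = df.pivot_table(
            index="compound", columns="cultivar", values="area_pct", aggfunc="std"
        )
        reps = df[["cultivar", "replicate", "compound", "area_pct"]].copy()
    else:
        piv = df.pivot_table(index="compound", columns="cultivar", values="area_pct")
        sd = None
        reps = None
    piv = piv.reindex(index=names, columns=cultivars).fillna(0.0)
    return CompositionTable(
        compounds=[recs[n] for n in names],
        means=piv,
        sds=None if sd is None else sd.reindex(index=names, columns=cultivars).fillna(0.0),
        replicates=reps,
    )


def write_composition_long(table: CompositionTable, path) -> None:
    """Write the replicate-level (or mean-level) table in the long CSV schema."""
    rows = []
    classes = {c.name: c.compound_class for c in table.compounds}
    if table.replicates is not None:
        for _, r in table.replicates.iterrows():
            rows.append(
                {
                    "cultivar": r["cultivar"],
                    "replicate": r["replicate"],
                    "compound": r["compound"],
                    "compound_class": classes.get(r["compound"], ""),
                    "area_pct": r["area_pct"],
                }
            )
    else:
        for cv in table.cultivars:
            for name, val in table.profile(cv).items():
                rows.append(
                    {
                        "cultivar": cv,
                        "replicate": "",
                        "compound": name,
                        "compound_class": classes.get(name, ""),
                        "area_pct": val,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_alkane_ladder(path) -> AlkaneLadder:
    """Read an alkane ladder CSV with columns ``carbon_number``, ``retention_time_min``."""
    df = pd.read_csv(path)
    return AlkaneLadder(
        dict(zip(df["carbon_number"].astype(int), df["retention_time_min"].astype(float)))
    )


def rosemary_panel() -> CompositionTable:
    """The packaged six-cultivar rosemary composition panel (mean ± SD)."""
    with resources.as_file(
        resources.files("eoscreen") / "data" / "rosemary_composition.csv"
    ) as p:
        return read_composition_wide(p)


#: The five constituents driving most of the mass and class separation in the
#: packaged rosemary panel.
MAIN_COMPONENTS = ("camphor", "verbenone", "α-pinene", "1,8-cineole", "bornyl acetate")
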