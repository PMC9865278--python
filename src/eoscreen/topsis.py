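"""TOPSIS: Technique for Order Preference by Similarity to an Ideal Solution.

Ranks *m* alternatives scored on *n* criteria by (1) vector-normalizing each
criterion column, (2) locating the positive/negative ideal solutions A+/A-
(per-column best/worst, with "best" depending on whether the criterion is a
benefit or a cost), (3) measuring each alternative's Euclidean separation
D+/D- from the two ideals, and (4) computing the closeness coefficient
``Ci = D- / (D+ + D-)`` in [0, 1]; rank 1 goes to the largest Ci.

The canonical procedure is unweighted; optional per-criterion weights are
supported as the standard variant that folds weights into the separation
distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import (
    DegenerateCriterionError,
    DegenerateIdealError,
    NegativeCriterionWarning,
    TieWarning,
)


@dataclass
class DecisionMatrix:
    """Alternatives × criteria matrix with per-criterion direction and weights."""

    values: pd.DataFrame
    directions: Sequence[str] | None = None
    weights: Sequence[float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        m, n = self.values.shape
        if m < 2 or n < 1:
            raise ValueError("need at least 2 alternatives and 1 criterion")
        if self.values.isna().any().any():
            raise ValueError("decision matrix must have no missing values")
        if self.directions is None:
            self.directions = ["benefit"] * n
        self.directions = list(self.directions)
        if len(self.directions) != n:
            raise ValueError("one direction per criterion required")
        for d in self.directions:
            if d not in ("benefit", "cost"):
                raise ValueError(f"direction must be benefit/cost, got {d!r}")
        if self.weights is not None:
            w = np.asarray(list(self.weights), float)
            if len(w) != n or np.any(w <= 0):
                raise ValueError("weights must be positive, one per criterion")
            if not np.isclose(w.sum(), 1.0):
                raise ValueError("weights must sum to 1")
            self.weights = w
        zero_cols = [
            c for c in self.values.columns if (self.values[c] == 0).all()
        ]
        if zero_cols:
            raise DegenerateCriterionError(
                f"all-zero criterion column(s): {zero_cols}"
            )

    @property
    def alternatives(self) -> list:
        return list(self.values.index)

    @property
    def criteria(self) -> list:
        return list(self.values.columns)


@dataclass(frozen=True)
class IdealSolutions:
    """Positive (A+) and negative (A-) ideal criterion vectors."""

    a_plus: np.ndarray
    a_minus: np.ndarray


@dataclass
class TopsisResult:
    """Full TOPSIS output: normalized matrix, ideals, separations, Ci, ranks."""

    normalized: pd.DataFrame
    ideals: IdealSolutions
    d_plus: pd.Series
    d_minus: pd.Series
    closeness: pd.Series
    rank: pd.Series
    ties: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Summary table mirroring the published layout (Di+, Di-, Ci, Ranking)."""
        return pd.DataFrame(
            {
                "d_plus": self.d_plus,
                "d_minus": self.d_minus,
                "closeness": self.closeness,
                "rank": self.rank,
            }
        )


def vector_normalize(values: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Normalize each criterion column to unit Euclidean norm: r_ij = x_ij/||x_.j||."""
    arr = np.asarray(values, float)
    norms = np.sqrt((arr**2).sum(axis=0))
    if np.any(norms == 0):
        cols = (
            [c for c, nz in zip(values.columns, norms == 0) if nz]
            if isinstance(values, pd.DataFrame)
            else list(np.nonzero(norms == 0)[0])
        )
        raise DegenerateCriterionError(f"all-zero criterion column(s): {cols}")
    out = arr / norms
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def ideal_solutions(
    normalized: pd.DataFrame | np.ndarray, directions: Sequence[str]
) -> IdealSolutions:
    """Per-column best (A+) and worst (A-) values, direction-aware."""
    arr = np.asarray(normalized, float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("normalized matrix must be finite")
    hi, lo = arr.max(axis=0), arr.min(axis=0)
    benefit = np.array([d == "benefit" for d in directions])
    return IdealSolutions(
        a_plus=np.where(benefit, hi, lo), a_minus=np.where(benefit, lo, hi)
    )


def separation_distances(
    normalized: pd.DataFrame | np.ndarray,
    ideals: IdealSolutions,
    weights: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean separations of each alternative from A+ and A-.

    With weights, ``D±_i = sqrt(Σ_j w_j (r_ij - a±_j)^2)``; without, w_j = 1
    (the canonical unweighted form).
    """
    arr = np.asarray(normalized, float)
    w = np.ones(arr.shape[1]) if weights is None else np.asarray(list(weights), float)
    if len(w) != arr.shape[1]:
        raise ValueError("one weight per criterion required")
    d_plus = np.sqrt((w * (arr - ideals.a_plus) ** 2).sum(axis=1))
    d_minus = np.sqrt((w * (arr - ideals.a_minus) ** 2).sum(axis=1))
    return d_plus, d_minus


def closeness_coefficients(
    d_plus: Sequence[float], d_minus: Sequence[float]
) -> np.ndarray:
    """Closeness coefficient Ci = D-_i / (D+_i + D-_i), in [0, 1]."""
    dp = np.asarray(list(d_plus), float)
    dm = np.asarray(list(d_minus), float)
    denom = dp + dm
    if np.any(denom <= 0):
        raise DegenerateIdealError(
            "D+ and D- both zero for some alternative (A+ = A-)"
        )
    return dm / denom


def rank_alternatives(closeness: Sequence[float]) -> tuple[np.ndarray, bool]:
    """Ranks (1 = largest Ci), ties broken stably by input order.

    Returns the rank vector and a flag that is True when ties occurred.
    """
    ci = np.asarray(list(closeness), float)
    if not np.all(np.isfinite(ci)):
        raise ValueError("closeness values must be finite")
    order = np.argsort(-ci, kind="stable")
    ranks = np.empty(len(ci), dtype=int)
    ranks[order] = np.arange(1, len(ci) + 1)
    ties = len(np.unique(ci)) < len(ci)
    if ties:
        warnings.warn("tied closeness coefficients", TieWarning, stacklevel=2)
    return ranks, ties


class TopsisRanker(BaseEstimator):
    """Scikit-learn style TOPSIS ranker.

    Parameters
    ----------
    directions : sequence of {"benefit", "cost"} or "benefit", default "benefit"
        Per-criterion optimization direction; a single string applies to all.
    weights : sequence of float, optional
        Positive per-criterion weights summing to 1, folded into the
        separation distances.  None (default) reproduces the canonical
        unweighted procedure.
    shift_negative : bool, default False
        Shift each column with negative entries so its minimum becomes zero
        before normalization.  Off by default; negative data otherwise only
        triggers a warning.

    Attributes (after :meth:`fit`)
    ------------------------------
    normalized_, ideals_, d_plus_, d_minus_, closeness_, rank_, ties_, result_
    """

    def __init__(
        self,
        directions: Sequence[str] | str = "benefit",
        weights: Sequence[float] | None = None,
        shift_negative: bool = False,
    ) -> None:
        self.directions = directions
        self.weights = weights
        self.shift_negative = shift_negative

    def fit(self, X, y=None) -> "TopsisRanker":
        if isinstance(X, DecisionMatrix):
            dm = X
        else:
            df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
            dirs = (
                [self.directions] * df.shape[1]
                if isinstance(self.directions, str)
                else list(self.directions)
            )
            dm = DecisionMatrix(values=df, directions=dirs, weights=self.weights)
        values = dm.values.astype(float)
        if (values.to_numpy() < 0).any():
            if self.shift_negative:
                values = values - values.min(axis=0).clip(upper=0)
            else:
                warnings.warn(
                    "decision matrix has negative entries; ideal-point semantics "
                    "assume non-negative benefit data",
                    NegativeCriterionWarning,
                    stacklevel=2,
                )
        normalized = vector_normalize(values)
        ideals = ideal_solutions(normalized, dm.directions)
        d_plus, d_minus = separation_distances(normalized, ideals, dm.weights)
        ci = closeness_coefficients(d_plus, d_minus)
        ranks, ties = rank_alternatives(ci)
        idx = dm.values.index
        self.normalized_ = normalized
        self.ideals_ = ideals
        self.d_plus_ = pd.Series(d_plus, index=idx, name="d_plus")
        self.d_minus_ = pd.Series(d_minus, index=idx, name="d_minus")
        self.closeness_ = pd.Series(ci, index=idx, name="closeness")
        self.rank_ = pd.Series(ranks, index=idx, name="rank")
        self.ties_ = ties
        self.result_ = TopsisResult(
            normalized=normalized,
            ideals=ideals,
            d_plus=self.d_plus_,
            d_minus=self.d_minus_,
            closeness=self.closeness_,
            rank=self.rank_,
            ties=ties,
        )
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit and return the rank vector (1 = best)."""
        return self.fit(X).rank_.to_numpy()


def topsis(matrix: DecisionMatrix | pd.DataFrame, **kwargs) -> TopsisResult:
    """One-shot TOPSIS on a decision matrix; thin wrapper over TopsisRanker."""
    if isinstance(matrix, DecisionMatrix):
        ranker = TopsisRanker(
            directions=matrix.directions,
            weights=None if matrix.weights is None else list(matrix.weights),
            **kwargs,
        )
    else:
        ranker = TopsisRanker(**kwargs)
    return ranker.fit(matrix).result_


# ---------------------------------------------------------------------------
# I/O

def read_decision_matrix(path) -> DecisionMatrix:
    """Read a decision-matrix CSV.

    First column holds alternative labels; the header row holds criterion
    labels.  An optional row labelled ``direction`` gives benefit/cost per
    criterion, and an optional row labelled ``weight`` gives weights.
    """
    raw = pd.read_csv(path, index_col=0)
    directions = None
    weights = None
    if "direction" in raw.index:
        directions = [str(v).strip() for v in raw.loc["direction"]]
        raw = raw.drop(index="direction")
    if "weight" in raw.index:
        weights = [float(v) for v in raw.loc["weight"]]
        raw = raw.drop(index="weight")
    return DecisionMatrix(
        values=raw.astype(float), directions=directions, weights=weights
    )


def write_result_tsv(result: TopsisResult, path, ndigits: int = 4) -> None:
    """Write the summary table as TSV (Di+, Di-, Ci to ``ndigits``, integer rank)."""
    df = result.to_frame().copy()
    for col in ("d_plus", "d_minus", "closeness"):
        df[col] = df[col].round(ndigits)
    df.index.name = "alternative"
    df.to_csv(path, sep="\t")


def reference_separations() -> pd.DataFrame:
    """The packaged printed separation table of the rosemary antioxidant panel.

    Columns: d_plus, d_minus, ci_printed, rank_printed; index: cultivar.
    These are published separations, used to anchor the closeness/rank
    arithmetic — the upstream assay matrix behind them is not public.
    """
    with resources.as_file(
        resources.files("eoscreen") / "data" / "topsis_separations.csv"
    ) as p:
        return pd.read_csv(p, index_col=0)
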