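"""Four-parameter logistic (4PL) dose-response fitting and IC50 estimation.

The model, on concentration c > 0 (mg/mL), is

    f(c) = bottom + (top - bottom) / (1 + (c / x0)^hill)

with ``top > bottom`` and ``hill > 0`` for a viability curve that falls with
concentration; ``x0`` is the curve midpoint (the *relative* IC50).  The
*absolute* IC50 — the default here — is the concentration where the fitted
curve crosses 50% of vehicle-normalized viability:

    IC50_abs = x0 * ((top - bottom) / (50 - bottom) - 1)^(1 / hill)

Fitting is nonlinear least squares on log-concentration with a deterministic
multi-start grid over the hill slope; uncertainty comes from a
case-resampling bootstrap over replicate wells.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DegenerateDesignError, NotCrossedWarning, UnusableFitError

logger = logging.getLogger(__name__)

#: Deterministic multi-start grid over the hill slope.
HILL_STARTS = (0.5, 1.0, 2.0, 4.0)


def four_pl(c, bottom: float, top: float, x0: float, hill: float):
    """Evaluate the 4PL curve at concentration(s) ``c``."""
    c = np.asarray(c, float)
    return bottom + (top - bottom) / (1.0 + (c / x0) ** hill)


@dataclass
class DoseResponseSeries:
    """Concentration-viability series for one sample.

    ``data`` has columns ``concentration`` (mg/mL, > 0), ``replicate`` and
    ``viability`` (% of vehicle).  At least 4 distinct concentration levels
    are required for a 4PL fit.
    """

    data: pd.DataFrame
    sample_id: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        need = {"concentration", "viability"}
        if not need <= set(self.data.columns):
            raise ValueError(f"series needs columns {sorted(need)}")
        if "replicate" not in self.data.columns:
            self.data = self.data.assign(replicate=0)
        if (self.data["concentration"] <= 0).any():
            raise ValueError("concentrations must be strictly positive")

    @property
    def n_levels(self) -> int:
        return self.data["concentration"].nunique()

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.data["concentration"].to_numpy(float),
            self.data["viability"].to_numpy(float),
        )


@dataclass
class FourPLFit:
    """Fitted 4PL parameters with convergence flag and optional bootstrap CI."""

    bottom: float
    top: float
    ic50: float  # curve midpoint x0 (relative IC50), mg/mL
    hill: float
    rss: float
    converged: bool
    ic50_ci: tuple[float, float] | None = None

    def predict(self, c):
        return four_pl(c, self.bottom, self.top, self.ic50, self.hill)


class FourPLRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style 4PL dose-response regressor.

    Parameters
    ----------
    mode : {"absolute", "relative"}, default "absolute"
        IC50 convention used by :attr:`ic50_`: "absolute" solves f(c) = 50,
        "relative" reports the curve midpoint x0.
    max_nfev : int, default 2000
        Function-evaluation budget per start of the least-squares solver.

    Attributes (after :meth:`fit`)
    ------------------------------
    bottom_, top_, x0_, hill_, rss_, converged_, ic50_, fit_
    """

    def __init__(self, mode: str = "absolute", max_nfev: int = 2000) -> None:
        self.mode = mode
        self.max_nfev = max_nfev

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _residuals(theta, logc, y):
        bottom, top, logx0, loghill = theta
        return bottom + (top - bottom) / (
            1.0 + np.exp(np.exp(loghill) * (logc - logx0))
        ) - y

    def _starts(self, logc, y):
        lo, hi = float(np.min(y)), float(np.max(y))
        mid = 0.5 * (lo + hi)
        # x0 init: log-concentration whose mean response is nearest mid-range;
        # depends on the data only through log-ratios, so it is exactly
        # scale-equivariant.
        levels = np.unique(logc)
        level_means = np.array([y[logc == l].mean() for l in levels])
        logx0 = float(levels[np.argmin(np.abs(level_means - mid))])
        for hill in HILL_STARTS:
            yield np.array([lo, hi, logx0, math.log(hill)])
        # a flat start guards the RSS-never-worse-than-flat-mean invariant
        ybar = float(np.mean(y))
        yield np.array([ybar, ybar + 1e-9, logx0, 0.0])

    def fit(self, X, y=None) -> "FourPLRegressor":
        if isinstance(X, DoseResponseSeries):
            c, y = X.arrays()
            n_levels = X.n_levels
        else:
            c = np.asarray(X, float).ravel()
            y = np.asarray(y, float).ravel()
            n_levels = len(np.unique(c))
        if n_levels < 4:
            raise DegenerateDesignError(
                f"need >= 4 distinct concentration levels, got {n_levels}"
            )
        if np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")

        ybar = float(np.mean(y))
        flat_rss = float(np.sum((y - ybar) ** 2))
        self.flat_rss_ = flat_rss
        if np.ptp(y) < 1e-10:
            self._set_flat(ybar, flat_rss)
            return self

        logc = np.log(c)
        best = None
        for theta0 in self._starts(logc, y):
            try:
                sol = least_squares(
                    self._residuals,
                    theta0,
                    args=(logc, y),
                    method="lm",
                    ftol=1e-14,
                    xtol=1e-14,
                    gtol=1e-14,
                    max_nfev=self.max_nfev,
                )
            except Exception:  # pragma: no cover - solver pathologies
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0] - 1e-15:
                best = (rss, sol.x)
        if best is None or best[0] > flat_rss + 1e-9:
            self._set_flat(ybar, flat_rss)
            return self

        rss, (bottom, top, logx0, loghill) = best
        hill = math.exp(loghill)
        x0 = math.exp(logx0)
        # canonical orientation keeps top > bottom; an inverted solution is the
        # same curve with the limits swapped and the hill slope negated
        if top < bottom:
            bottom, top, hill = top, bottom, -hill
        finite = all(map(math.isfinite, (bottom, top, x0, hill)))
        self.bottom_, self.top_, self.x0_, self.hill_ = bottom, top, x0, hill
        self.rss_ = rss
        self.converged_ = bool(finite and top > bottom and x0 > 0)
        self.fit_ = FourPLFit(
            bottom=self.bottom_,
            top=self.top_,
            ic50=self.x0_,
            hill=self.hill_,
            rss=self.rss_,
            converged=self.converged_,
        )
        self.ic50_ = self._ic50() if self.converged_ else float("nan")
        return self

    def _set_flat(self, ybar: float, flat_rss: float) -> None:
        self.bottom_ = self.top_ = ybar
        self.x0_ = float("nan")
        self.hill_ = float("nan")
        self.rss_ = flat_rss
        self.converged_ = False
        self.ic50_ = float("nan")
        self.fit_ = FourPLFit(
            bottom=ybar, top=ybar, ic50=float("nan"), hill=float("nan"),
            rss=flat_rss, converged=False,
        )

    def _ic50(self) -> float:
        if self.mode == "relative":
            return self.x0_
        return ic50_from_fit(self.fit_, mode="absolute")

    def predict(self, X) -> np.ndarray:
        c = np.asarray(X, float).ravel()
        return four_pl(c, self.bottom_, self.top_, self.x0_, self.hill_)


def fit_4pl(series: DoseResponseSeries, **kwargs) -> FourPLFit:
    """Fit a 4PL curve to a dose-response series; thin wrapper over FourPLRegressor."""
    return FourPLRegressor(**kwargs).fit(series).fit_


def ic50_from_fit(fit: FourPLFit, mode: str = "absolute") -> float:
    """IC50 from a converged 4PL fit.

    "relative" mode returns the curve midpoint x0.  "absolute" mode solves
    f(c) = 50 (% of vehicle); if the fitted curve never reaches 50, NaN is
    returned with a :class:`NotCrossedWarning`.
    """
    if not fit.converged:
        raise UnusableFitError("fit did not converge; IC50 undefined")
    if mode == "relative":
        return fit.ic50
    if mode != "absolute":
        raise ValueError(f"mode must be absolute/relative, got {mode!r}")
    if not (fit.bottom < 50.0 < fit.top):
        warnings.warn(
            "fitted curve does not cross 50% viability", NotCrossedWarning,
            stacklevel=2,
        )
        return float("nan")
    ratio = (fit.top - fit.bottom) / (50.0 - fit.bottom) - 1.0
    return fit.ic50 * ratio ** (1.0 / fit.hill)


def bootstrap_ci(
    series: DoseResponseSeries,
    n_boot: int = 1000,
    seed: int = 0,
    mode: str = "absolute",
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the IC50 by case-resampling wells within levels.

    Each bootstrap draw resamples, with replacement, the replicate wells
    within every concentration level, refits the curve (initialized at the
    original fit), and records the IC50.  Reproducible under a fixed seed.
    """
    if n_boot < 100:
        logger.warning("n_boot=%d is small; interval will be unstable", n_boot)
    base_est = FourPLRegressor(mode=mode).fit(series)
    if not base_est.converged_:
        raise UnusableFitError("original fit did not converge")
    theta0 = np.array(
        [
            base_est.bottom_,
            base_est.top_,
            math.log(base_est.x0_),
            math.log(base_est.hill_),
        ]
    )
    rng = np.random.default_rng(seed)
    df = series.data
    groups = [g.reset_index(drop=True) for _, g in df.groupby("concentration")]
    estimates = []
    for _ in range(n_boot):
        parts = [g.iloc[rng.integers(0, len(g), len(g))] for g in groups]
        boot = pd.concat(parts, ignore_index=True)
        logc = np.log(boot["concentration"].to_numpy(float))
        yv = boot["viability"].to_numpy(float)
        try:
            sol = least_squares(
                FourPLRegressor._residuals, theta0, args=(logc, yv),
                method="lm", max_nfev=500,
            )
        except Exception:
            continue
        bottom, top, logx0, loghill = sol.x
        hill = math.exp(loghill)
        if top < bottom:
            bottom, top, hill = top, bottom, -hill
        fit = FourPLFit(
            bottom=bottom, top=top, ic50=math.exp(logx0), hill=hill,
            rss=float(np.sum(sol.fun**2)), converged=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NotCrossedWarning)
            est = ic50_from_fit(fit, mode=mode)
        if math.isfinite(est):
            estimates.append(est)
    if not estimates:
        raise UnusableFitError("no bootstrap refit produced a usable IC50")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(estimates, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# I/O

def read_dose_response(path) -> list[DoseResponseSeries]:
    """Read a dose-response CSV (sample_id, concentration_mg_ml, replicate, viability_pct)."""
    df = pd.read_csv(path)
    out = []
    for sid, sub in df.groupby("sample_id"):
        out.append(
            DoseResponseSeries(
                data=sub.rename(
                    columns={
                        "concentration_mg_ml": "concentration",
                        "viability_pct": "viability",
                    }
                )[["concentration", "replicate", "viability"]].reset_index(drop=True),
                sample_id=str(sid),
            )
        )
    return out


def fit_summary(fit: FourPLFit, mode: str = "absolute", seed: int | None = None) -> dict:
    """JSON-serializable summary of a fit (parameters, IC50, CI, convergence)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NotCrossedWarning)
        ic50 = ic50_from_fit(fit, mode=mode) if fit.converged else None
    return {
        "bottom": fit.bottom,
        "top": fit.top,
        "x0": fit.ic50 if math.isfinite(fit.ic50) else None,
        "hill": fit.hill if math.isfinite(fit.hill) else None,
        "rss": fit.rss,
        "converged": fit.converged,
        "mode": mode,
        "ic50_mg_ml": None if ic50 is None or not math.isfinite(ic50) else ic50,
        "ic50_ci": list(fit.ic50_ci) if fit.ic50_ci else None,
        "seed": seed,
    }
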