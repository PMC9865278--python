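"""Component screening and composition-activity association.

Three complementary tools link a composition matrix (samples × compounds) to
activity endpoints:

* **OPLS-DA** — orthogonal partial least squares discriminant analysis.  The
  class-predictive variation is separated from structured variation
  orthogonal to the class labels (Trygg-Wold orthogonal signal correction),
  and per-variable **VIP** scores (variable importance in projection)
  summarize how much each compound contributes to the discrimination; by
  construction the mean squared VIP over the p variables equals 1, so
  VIP > 1 marks an above-average discriminator.
* **Spearman correlation matrices** with tie-corrected rho and exact
  permutation p-values at small n (full enumeration of rank permutations
  for n <= 8, where the t-approximation is unreliable).
* **Random-forest regression importance** on a scalar response (e.g. the
  TOPSIS closeness coefficient), measured as node purity: the decrease in
  node residual sum of squares attributed to splits on each variable,
  averaged over trees.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestRegressor

from .errors import DegenerateDesignError, DegenerateResponseWarning

# ---------------------------------------------------------------------------
# Spearman correlation with small-n exact permutation p-values


@dataclass
class SpearmanResult:
    """Pairwise Spearman correlations with p-values and significance stars."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    stars: pd.DataFrame

    def strongest_pair(self) -> tuple[str, str, float]:
        """(row, column, rho) of the largest finite |rho| off the self-diagonal."""
        best = None
        for r in self.rho.index:
            for c in self.rho.columns:
                v = self.rho.loc[r, c]
                if r == c or not np.isfinite(v):
                    continue
                if best is None or abs(v) > abs(best[2]):
                    best = (r, c, float(v))
        if best is None:
            raise ValueError("no finite off-diagonal correlation")
        return best


def significance_stars(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v)


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt((rxc**2).sum() * (ryc**2).sum())
    if denom == 0:
        return float("nan")
    return float((rxc * ryc).sum() / denom)


def exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value of the Spearman rho of (x, y).

    Enumerates all n! permutations of the y-ranks (tie structure preserved)
    and reports the fraction with |rho| at least as large as observed.
    """
    rx, ry = _rank(np.asarray(x, float)), _rank(np.asarray(y, float))
    obs = _rho_of_ranks(rx, ry)
    if not np.isfinite(obs):
        return float("nan")
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum(axis=1))
    rhos = (ryc @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(obs) - 1e-12))


def spearman_pair(x, y, exact_n_max: int = 8) -> tuple[float, float]:
    """Tie-corrected Spearman rho and p-value for one pair of vectors.

    Exact permutation p for n <= ``exact_n_max``; the usual t-approximation
    otherwise.  A constant input yields (nan, nan).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise DegenerateDesignError("need paired observations with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho = _rho_of_ranks(_rank(x), _rank(y))
    if len(x) <= exact_n_max:
        p = exact_spearman_p(x, y)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def spearman_matrix(
    x: pd.DataFrame, y: pd.DataFrame | None = None, exact_n_max: int = 8
) -> SpearmanResult:
    """Pairwise Spearman matrix between columns of ``x`` and ``y``.

    With ``y=None``, the symmetric self-correlation of ``x``'s columns
    (diagonal 1).  Rows of the result index ``x`` columns, columns index
    ``y`` columns.  Pairs with a constant member are reported as NaN
    (undefined correlation).
    """
    symmetric = y is None
    ydf = x if symmetric else y
    common = x.index.intersection(ydf.index)
    if len(common) < 3:
        raise DegenerateDesignError("fewer than 3 shared samples")
    xv = x.loc[common]
    yv = ydf.loc[common]
    rho = pd.DataFrame(np.nan, index=x.columns, columns=ydf.columns)
    p = pd.DataFrame(np.nan, index=x.columns, columns=ydf.columns)
    for xi in x.columns:
        for yi in ydf.columns:
            if symmetric and xi == yi:
                r_, p_ = (1.0, 0.0) if np.ptp(xv[xi].to_numpy()) > 0 else (np.nan, np.nan)
            elif symmetric and rho.index.get_loc(yi) < rho.columns.get_loc(xi):
                r_, p_ = rho.loc[yi, xi], p.loc[yi, xi]
            else:
                r_, p_ = spearman_pair(
                    xv[xi].to_numpy(), yv[yi].to_numpy(), exact_n_max
                )
            rho.loc[xi, yi] = r_
            p.loc[xi, yi] = p_
    stars = p.map(significance_stars) if hasattr(p, "map") else p.applymap(significance_stars)
    n = pd.DataFrame(len(common), index=rho.index, columns=rho.columns)
    return SpearmanResult(rho=rho, p=p, n=n, stars=stars)


# ---------------------------------------------------------------------------
# OPLS-DA


class OPLSDA(TransformerMixin, BaseEstimator):
    """Orthogonal PLS discriminant analysis with a one-hot class response.

    Structured variation orthogonal to the class labels is removed
    iteratively (``n_orthogonal`` components) before predictive PLS2
    components are extracted from the filtered matrix, so the predictive
    scores carry only between-class variation.

    Parameters
    ----------
    n_predictive : int or None
        Number of predictive components; None (default) uses
        ``n_classes - 1``.
    n_orthogonal : int, default 1
        Number of orthogonal components to strip.
    scaling : {"pareto", "uv", "none"}, default "pareto"
        Column scaling after mean-centering.  Pareto (divide by sqrt(SD))
        keeps abundance ordering in play and is the default: on
        relative-area composition data, unit-variance scaling lets
        near-binary trace compounds (perfect presence/absence class
        markers) saturate the discrimination, drowning the abundant
        drivers.
    cross_validate : bool, default True
        Compute leave-one-out Q2 (cross-validated R2Y).

    Attributes (after :meth:`fit`)
    ------------------------------
    classes_, weights_, scores_, loadings_, y_loadings_, orth_weights_,
    orth_scores_, orth_loadings_, ssy_, r2x_, r2y_, q2_, x_mean_, x_scale_,
    feature_names_
    """

    def __init__(
        self,
        n_predictive: int | None = None,
        n_orthogonal: int = 1,
        scaling: str = "pareto",
        cross_validate: bool = True,
        max_iter: int = 500,
        tol: float = 1e-12,
    ) -> None:
        self.n_predictive = n_predictive
        self.n_orthogonal = n_orthogonal
        self.scaling = scaling
        self.cross_validate = cross_validate
        self.max_iter = max_iter
        self.tol = tol

    # -- helpers -----------------------------------------------------------

    def _encode(self, y) -> tuple[np.ndarray, np.ndarray]:
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise DegenerateDesignError("OPLS-DA needs at least 2 classes")
        counts = {c: int((y == c).sum()) for c in classes}
        small = [c for c, k in counts.items() if k < 2]
        if small:
            raise DegenerateDesignError(
                f"classes with fewer than 2 samples: {small}"
            )
        Y = (y[:, None] == classes[None, :]).astype(float)
        return classes, Y

    def _scale_factors(self, X: np.ndarray) -> np.ndarray:
        sd = X.std(axis=0, ddof=1)
        if self.scaling == "uv":
            return sd
        if self.scaling == "pareto":
            return np.sqrt(sd)
        if self.scaling == "none":
            return np.ones(X.shape[1])
        raise ValueError(f"unknown scaling {self.scaling!r}")

    @staticmethod
    def _dominant_weight(Xc: np.ndarray, Yc: np.ndarray) -> np.ndarray:
        cov = Xc.T @ Yc
        u, s, _ = np.linalg.svd(cov, full_matrices=False)
        return u[:, 0]

    def _pls2_component(self, Xc, Yc):
        """One PLS2 component by NIPALS; returns (w, t, p, c)."""
        u = Yc[:, int(np.argmax(Yc.var(axis=0)))].copy()
        w = None
        for _ in range(self.max_iter):
            w_new = Xc.T @ u / (u @ u)
            nrm = np.linalg.norm(w_new)
            if nrm == 0:
                return None
            w_new /= nrm
            t = Xc @ w_new
            c = Yc.T @ t / (t @ t)
            u_new = Yc @ c / (c @ c)
            if w is not None and np.linalg.norm(w_new - w) < self.tol:
                w, u = w_new, u_new
                break
            w, u = w_new, u_new
        t = Xc @ w
        p = Xc.T @ t / (t @ t)
        c = Yc.T @ t / (t @ t)
        return w, t, p, c

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y) -> "OPLSDA":
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        names = list(Xdf.columns)
        Xa = Xdf.to_numpy(float)
        if Xa.shape[1] < 2:
            raise DegenerateDesignError("need at least 2 variables")
        self.classes_, Y = self._encode(y)

        sd = Xa.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            dropped = [n for n, k in zip(names, keep) if not k]
            warnings.warn(
                f"dropping zero-variance variable(s): {dropped}", UserWarning,
                stacklevel=2,
            )
            Xa = Xa[:, keep]
            names = [n for n, k in zip(names, keep) if k]
        self.feature_names_ = names

        self.x_mean_ = Xa.mean(axis=0)
        self.x_scale_ = self._scale_factors(Xa)
        Xc = (Xa - self.x_mean_) / self.x_scale_
        self.y_mean_ = Y.mean(axis=0)
        Yc = Y - self.y_mean_
        ssx_total = float((Xc**2).sum())
        ssy_total = float((Yc**2).sum())

        # orthogonal signal correction: strip variation orthogonal to the
        # whole class-predictive weight subspace (all Y-covariance
        # directions, not just the dominant one — essential for K > 2)
        orth_w, orth_t, orth_p = [], [], []
        for _ in range(self.n_orthogonal):
            cov = Xc.T @ Yc
            u, s, _ = np.linalg.svd(cov, full_matrices=False)
            r = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
            if r == 0:
                break
            W_basis = u[:, :r]
            w = W_basis[:, 0]
            t = Xc @ w
            p_load = Xc.T @ t / (t @ t)
            w_o = p_load - W_basis @ (W_basis.T @ p_load)
            nrm = np.linalg.norm(w_o)
            if nrm < 1e-12:
                break
            w_o /= nrm
            t_o = Xc @ w_o
            p_o = Xc.T @ t_o / (t_o @ t_o)
            Xc = Xc - np.outer(t_o, p_o)
            orth_w.append(w_o)
            orth_t.append(t_o)
            orth_p.append(p_o)
        self.orth_weights_ = np.array(orth_w).T if orth_w else np.empty((Xa.shape[1], 0))
        self.orth_scores_ = np.array(orth_t).T if orth_t else np.empty((Xa.shape[0], 0))
        self.orth_loadings_ = np.array(orth_p).T if orth_p else np.empty((Xa.shape[1], 0))

        # predictive PLS2 components on the filtered matrix
        n_pred = self.n_predictive
        if n_pred is None:
            n_pred = len(self.classes_) - 1
        n_pred = max(1, min(n_pred, Xa.shape[1], Xa.shape[0] - 1))
        W, T, P, C, ssy = [], [], [], [], []
        for _ in range(n_pred):
            comp = self._pls2_component(Xc, Yc)
            if comp is None:
                break
            w, t, p_load, c = comp
            if (t @ t) < 1e-14:
                break
            ssy_a = float((t @ t) * (c @ c))
            Xc = Xc - np.outer(t, p_load)
            Yc = Yc - np.outer(t, c)
            W.append(w)
            T.append(t)
            P.append(p_load)
            C.append(c)
            ssy.append(ssy_a)
        if not W:
            raise DegenerateDesignError("no predictive variation found")
        self.weights_ = np.array(W).T
        self.scores_ = np.array(T).T
        self.loadings_ = np.array(P).T
        self.y_loadings_ = np.array(C).T
        self.ssy_ = np.array(ssy)

        self.r2x_ = 1.0 - float((Xc**2).sum()) / ssx_total
        self.r2y_ = float(self.ssy_.sum()) / ssy_total if ssy_total > 0 else 0.0
        self.q2_ = self._loo_q2(Xdf[names].to_numpy(float), np.asarray(y)) if self.cross_validate else None
        return self

    def _project(self, Xa: np.ndarray) -> np.ndarray:
        """Predictive scores of (already raw) samples, applying the stored filter."""
        Xc = (Xa - self.x_mean_) / self.x_scale_
        for k in range(self.orth_weights_.shape[1]):
            t_o = Xc @ self.orth_weights_[:, k]
            Xc = Xc - np.outer(t_o, self.orth_loadings_[:, k])
        T = np.empty((Xc.shape[0], self.weights_.shape[1]))
        for a in range(self.weights_.shape[1]):
            t = Xc @ self.weights_[:, a]
            Xc = Xc - np.outer(t, self.loadings_[:, a])
            T[:, a] = t
        return T

    def transform(self, X) -> np.ndarray:
        """Predictive component scores of new samples."""
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        if isinstance(X, pd.DataFrame):
            Xa = Xdf[self.feature_names_].to_numpy(float)
        else:
            Xa = Xdf.to_numpy(float)
        return self._project(Xa)

    def predict_response(self, X) -> np.ndarray:
        """Predicted (one-hot, centered-back) class response of new samples."""
        T = self.transform(X)
        return T @ self.y_loadings_.T + self.y_mean_

    def predict(self, X) -> np.ndarray:
        """Hard class assignment: argmax of the predicted response."""
        return self.classes_[np.argmax(self.predict_response(X), axis=1)]

    def _loo_q2(self, Xa: np.ndarray, y: np.ndarray) -> float | None:
        """Leave-one-out Q2 of the class response."""
        n = Xa.shape[0]
        classes, Y = self._encode(y)
        press = 0.0
        params = self.get_params()
        params["cross_validate"] = False
        for i in range(n):
            mask = np.ones(n, bool)
            mask[i] = False
            if min(np.bincount(np.searchsorted(classes, y[mask]))) < 2:
                return None
            try:
                sub = OPLSDA(**params).fit(Xa[mask], y[mask])
                yhat = sub.predict_response(Xa[i : i + 1])[0]
            except DegenerateDesignError:
                return None
            # align the fold's class columns with the full encoding
            yhat_full = np.zeros(len(classes))
            for j, c in enumerate(sub.classes_):
                yhat_full[np.searchsorted(classes, c)] = yhat[j]
            press += float(((Y[i] - yhat_full) ** 2).sum())
        ssy = float(((Y - Y.mean(axis=0)) ** 2).sum())
        return 1.0 - press / ssy if ssy > 0 else None

    def summary(self) -> dict:
        """Model-fit summary (explained variation and component counts)."""
        return {
            "n_predictive": int(self.weights_.shape[1]),
            "n_orthogonal": int(self.orth_weights_.shape[1]),
            "scaling": self.scaling,
            "r2x": self.r2x_,
            "r2y": self.r2y_,
            "q2": self.q2_,
            "classes": [str(c) for c in self.classes_],
        }


def fit_opls_da(
    x: pd.DataFrame,
    labels,
    n_orth: int = 1,
    scaling: str = "pareto",
    n_predictive: int | None = None,
    **kwargs,
) -> OPLSDA:
    """Fit an OPLS-DA model; thin wrapper over :class:`OPLSDA`."""
    return OPLSDA(
        n_predictive=n_predictive, n_orthogonal=n_orth, scaling=scaling, **kwargs
    ).fit(x, labels)


def vip_scores(model: OPLSDA) -> pd.Series:
    """Variable importance in projection over the predictive components.

    ``VIP_j = sqrt(p * Σ_a(w_aj² · SSY_a) / Σ_a SSY_a)`` with unit-norm
    weight vectors w_a and SSY_a the Y sum of squares explained by component
    a.  Satisfies ``Σ_j VIP_j² = p``.
    """
    W = model.weights_
    ssy = model.ssy_
    p = W.shape[0]
    vip = np.sqrt(p * (W**2 @ ssy) / ssy.sum())
    return pd.Series(vip, index=model.feature_names_, name="vip")


def screen_components(vip: pd.Series, threshold: float = 1.0) -> list[str]:
    """Component names with VIP above ``threshold``, sorted by VIP descending."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    hits = vip[vip > threshold].sort_values(ascending=False)
    return list(hits.index)


# ---------------------------------------------------------------------------
# Random-forest node-purity importance


@dataclass
class RfImportance:
    """Per-variable node-purity importance from a random-forest regression."""

    importances: pd.Series  # mean decrease in node RSS per tree
    n_trees: int
    seed: int
    oob_mse: float | None

    def top(self, k: int = 5) -> list[str]:
        return list(self.importances.sort_values(ascending=False).index[:k])


class NodePurityForest(BaseEstimator):
    """Random-forest regressor reporting node-purity variable importance.

    Wraps :class:`sklearn.ensemble.RandomForestRegressor` (500 trees,
    ``max_features=1/3`` — the regression convention, bootstrap resampling)
    and measures each variable's importance as the decrease in node residual
    sum of squares attributed to splits on it, summed within a tree and
    averaged over trees.  Bit-identical under a fixed seed.
    """

    def __init__(self, n_trees: int = 500, seed: int = 0, max_features: float = 1 / 3) -> None:
        self.n_trees = n_trees
        self.seed = seed
        self.max_features = max_features

    def fit(self, X, y) -> "NodePurityForest":
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        ya = np.asarray(y, float)
        if Xdf.shape[0] < 4:
            raise DegenerateDesignError("need at least 4 samples")
        if np.ptp(ya) == 0:
            warnings.warn(
                "constant response; importances are all zero",
                DegenerateResponseWarning,
                stacklevel=2,
            )
        rf = RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            bootstrap=True,
            oob_score=Xdf.shape[0] >= 10,
            random_state=self.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sparse-OOB warnings at small n
            rf.fit(Xdf.to_numpy(float), ya)
        p = Xdf.shape[1]
        total = np.zeros(p)
        for est in rf.estimators_:
            tree = est.tree_
            internal = tree.children_left != -1
            nodes = np.nonzero(internal)[0]
            left, right = tree.children_left[nodes], tree.children_right[nodes]
            rss = tree.weighted_n_node_samples * tree.impurity
            dec = rss[nodes] - rss[left] - rss[right]
            np.add.at(total, tree.feature[nodes], dec)
        oob_mse = None
        if getattr(rf, "oob_prediction_", None) is not None:
            pred = rf.oob_prediction_
            ok = np.isfinite(pred)
            if ok.any():
                oob_mse = float(np.mean((ya[ok] - pred[ok]) ** 2))
        self.forest_ = rf
        self.importances_ = pd.Series(
            total / self.n_trees, index=Xdf.columns, name="inc_node_purity"
        )
        self.oob_mse_ = oob_mse
        self.result_ = RfImportance(
            importances=self.importances_,
            n_trees=self.n_trees,
            seed=self.seed,
            oob_mse=oob_mse,
        )
        return self

    def predict(self, X) -> np.ndarray:
        return self.forest_.predict(np.asarray(X, float))


def rf_regression_importance(
    x: pd.DataFrame, y, n_trees: int = 500, seed: int = 0
) -> RfImportance:
    """Node-purity importances of ``x``'s columns for predicting ``y``."""
    return NodePurityForest(n_trees=n_trees, seed=seed).fit(x, y).result_
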