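"""Two-block PLS regression of regional MS on age and PAL performance.

PLS2 with sequential deflation relates a subjects × regions predictor block
to a subjects × 2 outcome block (age, PAL total errors).  Both blocks are
z-scored (age in years and error counts live on different scales).
Significance of the outcome-block variance explained per component is
assessed by refitting under row-shuffled outcomes; scores and loadings are
sign-aligned so every component correlates non-negatively with the first
outcome column.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.validation import check_is_fitted

from .network import map_correlation
from .simulate import as_rng

__all__ = ["PLSBrainCognition", "permutation_significance",
           "score_outcome_correlations", "group_score_comparison",
           "loading_map_correlation"]


def _zscore_cols(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    return (x - x.mean(axis=0)) / sd


class PLSBrainCognition(TransformerMixin, BaseEstimator):
    """PLS2 of a regional-MS block against a 2-column outcome block.

    Attributes (after fit)
    ----------------------
    x_weights_, x_loadings_ : per-region weights/loadings, one column per
        component.
    y_loadings_ : outcome loadings.
    x_scores_ : subject scores (n × n_components).
    pct_var_y_ : % of outcome-block variance explained per component.
    cum_pct_var_y_ : running total of ``pct_var_y_``.
    regions_ : predictor column labels (constant columns dropped, warned).
    """

    def __init__(self, n_components: int = 2, tol: float = 1e-22,
                 max_iter: int = 3000):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, Y):
        if isinstance(X, pd.DataFrame):
            regions = np.array(X.columns)
            Xv = X.to_numpy(float)
        else:
            Xv = np.asarray(X, float)
            regions = np.array([f"region_{i}" for i in range(Xv.shape[1])])
        Yv = np.asarray(Y, float)
        if Yv.ndim == 1:
            Yv = Yv[:, None]
        if Xv.shape[0] <= self.n_components:
            raise ValueError("need more subjects than components")
        if np.any(Yv.std(axis=0) == 0):
            raise ValueError("constant outcome column")
        keep = Xv.std(axis=0) > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} constant predictor "
                          "column(s)", stacklevel=2)
        Xv = Xv[:, keep]
        self.regions_ = regions[keep].tolist()
        Xz = _zscore_cols(Xv)
        Yz = _zscore_cols(Yv)
        pls = PLSRegression(n_components=self.n_components, scale=False,
                            tol=self.tol, max_iter=self.max_iter)
        with warnings.catch_warnings():
            # the tight inner tolerance may not be reachable when the two
            # leading cross-covariance directions are nearly degenerate;
            # the weights are still accurate to ~sqrt(eps) there
            warnings.simplefilter("ignore", ConvergenceWarning)
            pls.fit(Xz, Yz)
        t = pls.x_scores_                      # n x K, mutually orthogonal
        w = pls.x_weights_
        p = pls.x_loadings_
        # outcome loadings: regression of (standardized) Y on each score
        tt = np.sum(t ** 2, axis=0)
        q = (Yz.T @ t) / tt                    # n_outcomes x K
        # sign alignment against the first outcome column
        flip = np.where(q[0] < 0, -1.0, 1.0)
        t = t * flip
        w = w * flip
        p = p * flip
        q = q * flip
        ss_tot = float(np.sum(Yz ** 2))
        pct = 100.0 * (np.sum(q ** 2, axis=0) * tt) / ss_tot
        self.x_scores_ = t
        self.x_weights_ = w
        self.x_loadings_ = p
        self.y_loadings_ = q.T                 # K x n_outcomes -> transposed
        self.pct_var_y_ = pct
        self.cum_pct_var_y_ = np.cumsum(pct)
        self.n_features_in_ = Xv.shape[1]
        self._x_mean = Xv.mean(axis=0)
        self._x_sd = Xv.std(axis=0, ddof=1)
        return self

    def transform(self, X):
        check_is_fitted(self, "x_weights_")
        if isinstance(X, pd.DataFrame):
            X = X[self.regions_].to_numpy(float)
        Xz = (np.asarray(X, float) - self._x_mean) / self._x_sd
        # scores via the weight rotation (deflation-consistent)
        rot = self.x_weights_ @ np.linalg.pinv(
            self.x_loadings_.T @ self.x_weights_)
        return Xz @ rot

    def loadings_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "x_loadings_")
        cols = {f"component_{k + 1}": self.x_loadings_[:, k]
                for k in range(self.n_components)}
        return pd.DataFrame({"region": self.regions_, **cols})


def _fit_pct(X, Y, n_components):
    """Total and per-component % outcome variance for permutation calls."""
    model = PLSBrainCognition(n_components=n_components).fit(X, Y)
    return model.pct_var_y_


def permutation_significance(model: PLSBrainCognition, X, Y,
                             n_perm: int = 5000, seed: int = 0) -> np.ndarray:
    """Permutation p per component for % outcome variance explained.

    Outcome rows are shuffled jointly (preserving the age–PAL coupling);
    p uses the add-one estimator, so the minimum attainable value is
    1/(n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse p-value grid",
                      stacklevel=2)
    check_is_fitted(model, "pct_var_y_")
    rng = as_rng(seed)
    Yv = np.asarray(Y, float)
    if Yv.ndim == 1:
        Yv = Yv[:, None]
    observed = model.pct_var_y_
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        perm = rng.permutation(Yv.shape[0])
        null = _fit_pct(X, Yv[perm], model.n_components)
        exceed += null >= observed
    return (1.0 + exceed) / (1.0 + n_perm)


def score_outcome_correlations(model: PLSBrainCognition,
                               outcomes: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (and p) between each component's scores and each outcome."""
    check_is_fitted(model, "x_scores_")
    rows = []
    for k in range(model.n_components):
        for name in outcomes.columns:
            r, p = stats.pearsonr(model.x_scores_[:, k],
                                  outcomes[name].to_numpy(float))
            rows.append({"component": k + 1, "outcome": name,
                         "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def group_score_comparison(model: PLSBrainCognition, groups,
                           group_a: str = "patient",
                           group_b: str = "control",
                           n_perm: int = 5000, seed: int = 0) -> pd.DataFrame:
    """Two-sample t on component scores with label-permutation p."""
    check_is_fitted(model, "x_scores_")
    groups = np.asarray(groups)
    mask_a = groups == group_a
    mask_b = groups == group_b
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("both groups need at least 2 subjects")
    rng = as_rng(seed)
    rows = []
    for k in range(model.n_components):
        s = model.x_scores_[:, k]
        t, p = stats.ttest_ind(s[mask_a], s[mask_b])
        pool = s[mask_a | mask_b]
        na = mask_a.sum()
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(pool.size)
            t_null, _ = stats.ttest_ind(pool[perm[:na]], pool[perm[na:]])
            exceed += abs(t_null) >= abs(t)
        rows.append({"component": k + 1, "t": float(t), "p": float(p),
                     "perm_p": (1.0 + exceed) / (1.0 + n_perm),
                     "contrast": f"{group_a}_minus_{group_b}"})
    return pd.DataFrame(rows)


def loading_map_correlation(model: PLSBrainCognition, t_map: pd.Series,
                            n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Correlate each component's regional loadings with a t-statistic map."""
    check_is_fitted(model, "x_loadings_")
    rows = []
    for k in range(model.n_components):
        loadings = pd.Series(model.x_loadings_[:, k], index=model.regions_)
        res = map_correlation(loadings, t_map, n_perm=n_perm,
                              seed=seed + k)
        rows.append({"component": k + 1, "r": res["r"],
                     "perm_p": res.get("p_perm", np.nan)})
    return pd.DataFrame(rows)
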