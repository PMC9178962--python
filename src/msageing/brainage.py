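"""Brain-age prediction from regional MS and brain-age gaps.

A lasso (L1-penalized) linear model maps the 360 regional MS values to age;
the penalty is chosen by cross-validated prediction error on the normative
cohort.  The brain-age gap is predicted minus calendar age, so an
older-looking brain yields a positive gap (a flag flips the convention).

Raw gaps are negatively correlated with age on held-out data
(regression-to-the-mean); the training report quantifies this and an
optional linear correction removes it.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold, cross_val_predict
from sklearn.utils.validation import check_is_fitted

from .stats import cohens_d

__all__ = ["BrainAgeRegressor", "compute_gaps", "compare_gaps"]


class BrainAgeRegressor(RegressorMixin, BaseEstimator):
    """Sparse linear age model over regional MS.

    Parameters
    ----------
    cv_folds : folds for the penalty search (default 5).
    n_alphas : size of the logarithmic penalty grid.
    random_state : seeds the CV shuffle; coordinate descent is deterministic.
    fit_bias_correction : when True, a linear age-bias model is fit on
        out-of-fold training predictions and stored (not applied unless
        requested in :func:`compute_gaps`).

    Attributes
    ----------
    coef_, intercept_ : model weights (years per MS unit) and offset.
    alpha_ : selected penalty.
    n_zero_weights_ : sparsity of the solution.
    gap_age_corr_ : correlation of out-of-fold gaps with age (bias report).
    bias_slope_, bias_intercept_ : linear age-bias model (gap ~ age).
    """

    def __init__(self, cv_folds: int = 5, n_alphas: int = 50,
                 eps: float = 1e-2, random_state: int = 0,
                 fit_bias_correction: bool = True, max_iter: int = 2000):
        self.cv_folds = cv_folds
        self.n_alphas = n_alphas
        self.eps = eps
        self.random_state = random_state
        self.fit_bias_correction = fit_bias_correction
        self.max_iter = max_iter

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.regions_ = list(X.columns)
            X = X.to_numpy(float)
        else:
            X = np.asarray(X, float)
            self.regions_ = [f"region_{i}" for i in range(X.shape[1])]
        y = np.asarray(y, float).reshape(-1)
        if np.ptp(y) == 0:
            raise ValueError("age vector is constant; cannot train")
        if not 2 <= self.cv_folds <= len(y):
            raise ValueError("need n >= cv_folds >= 2")
        cv = KFold(self.cv_folds, shuffle=True,
                   random_state=self.random_state)
        model = LassoCV(alphas=self.n_alphas, eps=self.eps, cv=cv,
                        max_iter=self.max_iter,
                        random_state=self.random_state)
        with warnings.catch_warnings():
            # deep-penalty path segments on correlated regions may stop at
            # max_iter; the CV error there is already far past its minimum
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X, y)
        self.coef_ = model.coef_
        self.intercept_ = float(model.intercept_)
        self.alpha_ = float(model.alpha_)
        self.n_zero_weights_ = int(np.sum(model.coef_ == 0.0))
        # out-of-fold predictions at the selected penalty for the age-bias
        # report (refitting the whole penalty path per fold would give a
        # marginally less optimistic estimate at ~6x the cost)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            oof = cross_val_predict(
                Lasso(alpha=self.alpha_, max_iter=self.max_iter),
                X, y, cv=cv)
        gaps = oof - y
        self.oof_mae_ = float(np.mean(np.abs(gaps)))
        ss_res = float(np.sum(gaps ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.oof_r2_ = 1.0 - ss_res / ss_tot
        self.gap_age_corr_ = float(np.corrcoef(gaps, y)[0, 1])
        if self.fit_bias_correction:
            slope, intercept = np.polyfit(y, gaps, 1)
            self.bias_slope_ = float(slope)
            self.bias_intercept_ = float(intercept)
        self.n_features_in_ = X.shape[1]
        self.train_summary_ = {"n": int(len(y)),
                               "cv_folds": self.cv_folds,
                               "alpha": self.alpha_,
                               "n_zero_weights": self.n_zero_weights_,
                               "oof_mae": self.oof_mae_,
                               "oof_r2": self.oof_r2_,
                               "gap_age_corr": self.gap_age_corr_,
                               "seed": self.random_state}
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            missing = [r for r in self.regions_ if r not in X.columns]
            if missing:
                raise ValueError(f"regional MS table lacks model regions: "
                                 f"{missing[:5]}")
            X = X[self.regions_].to_numpy(float)
        X = np.asarray(X, float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("region count mismatch with the trained model")
        return X @ self.coef_ + self.intercept_

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {"weights": dict(zip(self.regions_, self.coef_.tolist())),
                "intercept": self.intercept_,
                "alpha": self.alpha_,
                "bias_slope": getattr(self, "bias_slope_", None),
                "bias_intercept": getattr(self, "bias_intercept_", None),
                "train_summary": self.train_summary_}


def compute_gaps(model: BrainAgeRegressor, regional_ms,
                 ages, subject_ids=None, convention: str = "predicted_minus_calendar",
                 bias_corrected: bool = False) -> pd.DataFrame:
    """Brain-age gaps for a cohort.

    ``convention`` may be flipped to ``"calendar_minus_predicted"``; the
    choice is recorded on the result.  ``bias_corrected`` subtracts the
    training-cohort linear age-bias trend from the gaps.
    """
    ages = np.asarray(ages, float).reshape(-1)
    predicted = model.predict(regional_ms)
    gap = predicted - ages
    if bias_corrected:
        if getattr(model, "bias_slope_", None) is None:
            raise ValueError("model was fit without bias correction")
        gap = gap - (model.bias_slope_ * ages + model.bias_intercept_)
    if convention == "calendar_minus_predicted":
        gap = -gap
    elif convention != "predicted_minus_calendar":
        raise ValueError(f"unknown gap convention {convention!r}")
    if subject_ids is None and isinstance(regional_ms, pd.DataFrame):
        subject_ids = regional_ms.index
    out = pd.DataFrame({"subject_id": subject_ids,
                        "predicted_age": predicted,
                        "calendar_age": ages,
                        "gap": gap})
    out.attrs["convention"] = convention
    out.attrs["bias_corrected"] = bias_corrected
    return out


def compare_gaps(gaps: pd.DataFrame, groups: pd.Series,
                 group_a: str = "patient", group_b: str = "control") -> dict:
    """Two-sample t-test on gaps; difference reported as A − B
    (patient − control by default)."""
    merged = gaps.merge(groups.rename("group"), left_on="subject_id",
                        right_index=True)
    a = merged.loc[merged["group"] == group_a, "gap"].to_numpy(float)
    b = merged.loc[merged["group"] == group_b, "gap"].to_numpy(float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 subjects")
    t, p = stats.ttest_ind(a, b)
    return {"difference_years": float(a.mean() - b.mean()),
            f"mean_{group_a}": float(a.mean()),
            f"mean_{group_b}": float(b.mean()),
            "t": float(t), "p": float(p),
            "cohens_d": cohens_d(a, b),
            "n": (int(a.size), int(b.size)),
            "contrast": f"{group_a}_minus_{group_b}"}
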