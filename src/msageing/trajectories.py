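"""Normative age trajectories of regional mean MS.

Per region, ordinary least squares fits a polynomial (degree 1–3) of age;
quadratics are the working model.  Regions whose fit has negative adjusted
R² are excluded from downstream deviation analysis.  Retained regions are
classified by the sign of the trajectory slope at an early (27 y) and late
(60 y) reference age into increasing / decreasing / convex / concave.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["NormativeTrajectoryModel", "fit_polynomial", "compare_degrees",
           "classify_trajectory", "turning_point", "predict_trajectory",
           "CATEGORIES"]

CATEGORIES = ("increasing", "decreasing", "convex", "concave")


def _design(ages: np.ndarray, degree: int, center: float) -> np.ndarray:
    x = ages - center
    return np.vander(x, degree + 1, increasing=True)


def _uncenter(coefs_centered: np.ndarray, center: float) -> np.ndarray:
    """Convert coefficients fit on (age − c) to the raw-age scale."""
    # columns are per-region polynomial coefficient vectors (ascending)
    out = np.zeros_like(coefs_centered)
    degree = coefs_centered.shape[0] - 1
    for r in range(coefs_centered.shape[1]):
        p = np.polynomial.Polynomial(coefs_centered[:, r])
        shifted = p(np.polynomial.Polynomial([-center, 1.0]))
        c = shifted.coef
        out[: c.size, r] = c
    return out


def _fit_ols(ages: np.ndarray, values: np.ndarray, degree: int):
    """Vectorized OLS over regions; returns raw-scale coefs and adjusted R²."""
    n = ages.size
    if n <= degree + 1:
        raise ValueError(f"need n > degree + 1 (= {degree + 1}) subjects")
    if np.ptp(ages) == 0:
        raise ValueError("ages are all equal; design is rank-deficient")
    center = float(ages.mean())
    design = _design(ages, degree, center)
    rank = np.linalg.matrix_rank(design)
    if rank < degree + 1:
        raise ValueError("rank-deficient design (too few distinct ages)")
    coefs_c, _, _, _ = np.linalg.lstsq(design, values, rcond=None)
    fitted = design @ coefs_c
    resid = values - fitted
    ss_res = np.sum(resid ** 2, axis=0)
    ss_tot = np.sum((values - values.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - degree - 1)
    return _uncenter(coefs_c, center), adj, ss_res


def fit_polynomial(ages, values, degree: int = 2):
    """Fit one region's polynomial age trajectory.

    Returns ``(coefficients ascending in age, adjusted R²)`` on the raw-age
    scale.  Adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1) with p = degree.
    """
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    ages = np.asarray(ages, float)
    values = np.asarray(values, float)
    y = values[:, None] if values.ndim == 1 else values
    coefs, adj, _ = _fit_ols(ages, y, degree)
    if values.ndim == 1:
        return coefs[:, 0], float(adj[0])
    return coefs, adj


def compare_degrees(ages, values, degrees=(1, 2, 3), alpha: float = 0.05,
                    majority: float = 0.5) -> dict:
    """Nested-model F-tests across polynomial degrees, per region and pooled.

    For consecutive degrees d−1 → d the F statistic is
    ``((RSS_{d−1} − RSS_d)/1) / (RSS_d/(n − d − 1))``.  The cohort-level
    degree is the largest degree whose improvement is significant at
    ``alpha`` in more than a ``majority`` share of regions.
    """
    ages = np.asarray(ages, float)
    y = np.asarray(values, float)
    y = y[:, None] if y.ndim == 1 else y
    n = ages.size
    degrees = sorted(degrees)
    rss = {}
    for d in degrees:
        _, _, ss = _fit_ols(ages, y, d)
        rss[d] = ss
    report = {"alpha": alpha, "majority": majority, "n_subjects": n,
              "tests": {}}
    selected = degrees[0]
    for lo, hi in zip(degrees[:-1], degrees[1:]):
        df_num = hi - lo
        df_den = n - hi - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((rss[lo] - rss[hi]) / df_num) / (rss[hi] / df_den)
        f = np.where(rss[hi] == 0, np.inf, f)
        p = stats.f.sf(f, df_num, df_den)
        p = np.where(np.isinf(f), 0.0, p)
        share = float(np.mean(p < alpha))
        report["tests"][f"{hi}_vs_{lo}"] = {
            "f": f.tolist() if f.size > 1 else float(f[0]),
            "p": p.tolist() if p.size > 1 else float(p[0]),
            "share_significant": share,
        }
        if share > majority:
            selected = hi
        else:
            break
    report["selected_degree"] = selected
    return report


def _slopes(a1, a2, age):
    return np.asarray(a1) + 2.0 * np.asarray(a2) * age


def classify_trajectory(a1: float, a2: float, early: float = 27.0,
                        late: float = 60.0) -> str:
    """Four-way shape class from slope signs at the two reference ages.

    Zero slope at a reference age counts as increasing there (measure-zero
    tie-break, fixed and documented).
    """
    s_early = _slopes(a1, a2, early) >= 0
    s_late = _slopes(a1, a2, late) >= 0
    return {(True, True): "increasing", (False, False): "decreasing",
            (True, False): "convex", (False, True): "concave"}[
        (bool(s_early), bool(s_late))]


def turning_point(a1: float, a2: float):
    """Age where the quadratic slope changes sign; None when a2 == 0."""
    if a2 == 0:
        return None
    return -a1 / (2.0 * a2)


def predict_trajectory(coefs, age):
    """Evaluate an ascending-coefficient polynomial at the given age(s)."""
    return np.polynomial.polynomial.polyval(np.asarray(age, float),
                                            np.asarray(coefs, float))


class NormativeTrajectoryModel(RegressorMixin, BaseEstimator):
    """Per-region polynomial age model of regional mean MS.

    A multi-output regressor: ``fit(X, y)`` takes ages (n,) or (n, 1) and a
    subject × region table of regional MS; ``predict(X)`` returns the
    per-region trajectory values at the requested ages.

    Parameters
    ----------
    degree : polynomial degree (default 2, the working model).
    early, late : reference ages (years) for shape classification.

    Attributes
    ----------
    coef_ : (n_regions, degree+1) raw-age-scale coefficients, ascending.
    adj_r2_ : adjusted R² per region.
    retained_ : boolean mask, ``adj_r2_ >= 0``.
    category_ : shape class per region (None where not retained).
    turning_point_ : −a1/(2 a2) per region (NaN where a2 == 0).
    regions_ : region labels in column order of the training table.
    """

    def __init__(self, degree: int = 2, early: float = 27.0,
                 late: float = 60.0):
        self.degree = degree
        self.early = early
        self.late = late

    def fit(self, X, y):
        ages = np.asarray(X, float).reshape(-1)
        if isinstance(y, pd.DataFrame):
            self.regions_ = list(y.columns)
            values = y.to_numpy(float)
        else:
            values = np.asarray(y, float)
            if values.ndim == 1:
                values = values[:, None]
            self.regions_ = [f"region_{i}" for i in range(values.shape[1])]
        if ages.size != values.shape[0]:
            raise ValueError("X and y have different numbers of subjects")
        coefs, adj, _ = _fit_ols(ages, values, self.degree)
        self.coef_ = coefs.T
        self.adj_r2_ = adj
        self.retained_ = adj >= 0
        self.n_subjects_ = ages.size
        self.age_range_ = (float(ages.min()), float(ages.max()))
        a1 = self.coef_[:, 1]
        a2 = (self.coef_[:, 2] if self.degree >= 2
              else np.zeros_like(a1))
        self.category_ = np.array(
            [classify_trajectory(b1, b2, self.early, self.late) if keep
             else None
             for b1, b2, keep in zip(a1, a2, self.retained_)], dtype=object)
        with np.errstate(divide="ignore", invalid="ignore"):
            tp = np.where(a2 != 0, -a1 / (2.0 * a2), np.nan)
        self.turning_point_ = tp
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        ages = np.asarray(X, float).reshape(-1)
        powers = np.vander(ages, self.degree + 1, increasing=True)
        return powers @ self.coef_.T

    def slope(self, age: float) -> np.ndarray:
        """First derivative of every region's trajectory at an age."""
        check_is_fitted(self, "coef_")
        deriv = np.arange(1, self.degree + 1)
        powers = np.asarray(age, float) ** (deriv - 1)
        return (self.coef_[:, 1:] * deriv * powers).sum(axis=1)

    def category_counts(self) -> dict:
        check_is_fitted(self, "category_")
        return {c: int(np.sum(self.category_ == c)) for c in CATEGORIES}

    def to_frame(self) -> pd.DataFrame:
        """Serializable per-region summary (the normative-model table)."""
        check_is_fitted(self, "coef_")
        cols = {f"a{i}": self.coef_[:, i] for i in range(self.degree + 1)}
        return pd.DataFrame(
            {"region": self.regions_, **cols, "adj_r2": self.adj_r2_,
             "retained": self.retained_,
             "category": [c if c is not None else "" for c in self.category_],
             "turning_point": self.turning_point_})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, early: float = 27.0,
                   late: float = 60.0) -> "NormativeTrajectoryModel":
        coef_cols = sorted(c for c in frame.columns if c.startswith("a")
                           and c[1:].isdigit())
        model = cls(degree=len(coef_cols) - 1, early=early, late=late)
        model.regions_ = frame["region"].tolist()
        model.coef_ = frame[coef_cols].to_numpy(float)
        model.adj_r2_ = frame["adj_r2"].to_numpy(float)
        model.retained_ = frame["retained"].astype(bool).to_numpy()
        model.category_ = np.array(
            [c if c else None for c in frame["category"]], dtype=object)
        model.turning_point_ = frame["turning_point"].to_numpy(float)
        model.n_features_in_ = 1
        return model
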