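"""Group statistics: regional case-control maps, effect sizes, FDR and the
behavioural (PAL) linear model.

FDR over the per-region hypothesis family uses Benjamini–Hochberg by default;
a Storey-style q-value (adaptive null proportion, as in MATLAB's ``mafdr``)
is available as an option.  Which procedure produced a ``q`` column is
recorded in the result's metadata.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import map_correlation
from .simulate import as_rng

__all__ = ["fdr_qvalues", "case_control_map", "cohens_d", "hub_relationship",
           "pal_model"]


def _storey_qvalues(p: np.ndarray) -> np.ndarray:
    """Storey q-values with the smoother-free median-lambda pi0 estimate."""
    p = np.asarray(p, float)
    m = p.size
    lambdas = np.arange(0.05, 0.95, 0.05)
    pi0 = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
    pi0 = min(1.0, float(np.median(pi0)))  # robust, conservative
    order = np.argsort(p)
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def fdr_qvalues(p, method: str = "bh") -> np.ndarray:
    """Multiple-testing q-values: ``"bh"`` (Benjamini–Hochberg, default) or
    ``"storey"`` (adaptive pi0)."""
    p = np.asarray(p, float)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        return _storey_qvalues(p)
    raise ValueError(f"unknown FDR method {method!r}")


def cohens_d(a, b) -> float:
    """(mean(a) − mean(b)) / pooled SD, pooled with (nA + nB − 2) weights."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    pooled_var = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                  / (na + nb - 2)) if na + nb > 2 else 0.0
    if pooled_var <= 0:
        return np.nan
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def case_control_map(regional_ms: pd.DataFrame, groups: pd.Series,
                     group_a: str = "control", group_b: str = "patient",
                     fdr_q: float = 0.01, n_perm: int = 0,
                     equal_var: bool = True, fdr_method: str = "bh",
                     seed: int = 0) -> pd.DataFrame:
    """Per-region two-sample t-tests between two groups (A minus B).

    Pooled-variance t by default (``equal_var=False`` for Welch).  Label
    permutation p-values (two-sided) are computed jointly across regions so
    the spatial correlation of the null is preserved.
    """
    groups = groups.reindex(regional_ms.index)
    mask_a = (groups == group_a).to_numpy()
    mask_b = (groups == group_b).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("both groups need at least 2 subjects")
    x = regional_ms.to_numpy(float)
    a, b = x[mask_a], x[mask_b]
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    q = fdr_qvalues(p, method=fdr_method)
    d = np.array([cohens_d(a[:, j], b[:, j]) for j in range(x.shape[1])])
    if n_perm > 0:
        rng = as_rng(seed)
        both = x[mask_a | mask_b]
        na = mask_a.sum()
        exceed = np.zeros(x.shape[1])
        for _ in range(n_perm):
            perm = rng.permutation(both.shape[0])
            t_null, _ = stats.ttest_ind(both[perm[:na]], both[perm[na:]],
                                        equal_var=equal_var)
            exceed += np.abs(t_null) >= np.abs(t)
        perm_p = (1.0 + exceed) / (1.0 + n_perm)
    else:
        perm_p = np.full(x.shape[1], np.nan)
    out = pd.DataFrame({"region": regional_ms.columns,
                        f"mean_{group_a}": a.mean(axis=0),
                        f"mean_{group_b}": b.mean(axis=0),
                        "t": t, "p": p, "q": q, "perm_p": perm_p,
                        "cohens_d": d,
                        "significant": q < fdr_q})
    out.attrs.update({"fdr_q": fdr_q, "fdr_method": fdr_method,
                      "equal_var": equal_var, "n_perm": n_perm,
                      "contrast": f"{group_a}_minus_{group_b}"})
    return out


def hub_relationship(t_map: pd.Series, hub_map: pd.Series,
                     n_perm: int = 1000, seed: int = 0) -> dict:
    """Correlate a case-control t map with the control-group mean MS map.

    A positive r with hub MS means hubs (high-MS regions) show the largest
    group differences.  Permutation p shuffles region labels.
    """
    return map_correlation(t_map, hub_map, n_perm=n_perm, seed=seed)


def _nested_f(rss_small, rss_big, df_drop, df_resid):
    f = ((rss_small - rss_big) / df_drop) / (rss_big / df_resid)
    p = stats.f.sf(f, df_drop, df_resid)
    return float(f), float(p)


def pal_model(behaviour: pd.DataFrame, demographics: pd.DataFrame,
              partition=None) -> dict:
    """Linear model of PAL total errors on group and age.

    Main-effect F tests come from the additive model (dropping one term at
    a time); the interaction F compares additive vs full.  A per-age-category
    Cohen's d table is attached when a partition is given.
    """
    df = behaviour.merge(demographics, on="subject_id")
    if df["group"].nunique() < 2:
        raise ValueError("need two groups for the PAL model")
    y = df["pal_total_errors"].to_numpy(float)
    age = df["age"].to_numpy(float)
    grp = (df["group"] == "patient").to_numpy(float)
    n = y.size

    def rss(design):
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        return float(np.sum((y - design @ coef) ** 2))

    ones = np.ones(n)
    add_design = np.column_stack([ones, age, grp])
    coef_add, _, _, _ = np.linalg.lstsq(add_design, y, rcond=None)
    rss_add = rss(add_design)
    rss_age = rss(np.column_stack([ones, age]))
    rss_grp = rss(np.column_stack([ones, grp]))
    rss_full = rss(np.column_stack([ones, age, grp, age * grp]))

    f_group, p_group = _nested_f(rss_age, rss_add, 1, n - 3)
    f_age, p_age = _nested_f(rss_grp, rss_add, 1, n - 3)
    f_inter, p_inter = _nested_f(rss_add, rss_full, 1, n - 4)

    result = {"n": n,
              "coefficients": {"intercept": float(coef_add[0]),
                               "age": float(coef_add[1]),
                               "group": float(coef_add[2])},
              "group": {"f": f_group, "p": p_group, "df": (1, n - 3)},
              "age": {"f": f_age, "p": p_age, "df": (1, n - 3)},
              "interaction": {"f": f_inter, "p": p_inter, "df": (1, n - 4)}}
    if partition is not None:
        table = {}
        for cat in partition:
            last = cat == max(partition, key=lambda c: c.hi)
            sel = (age >= cat.lo) & ((age < cat.hi) | (last & (age == cat.hi)))
            a = y[sel & (grp == 1)]
            b = y[sel & (grp == 0)]
            if a.size >= 2 and b.size >= 2:
                table[cat.label] = cohens_d(a, b)
        result["cohens_d_by_category"] = table
    return result
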