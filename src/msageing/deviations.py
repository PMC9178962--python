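"""Deviations from normative trajectories and accelerated-ageing consistency.

A subject's deviation in a region is observed regional MS minus the value the
normative trajectory predicts at their age (this sign makes the direction
rules self-consistent: on a declining trajectory, an "older-looking" region
sits *below* the curve, so negative deviations indicate accelerated ageing).

Deviations are grouped into age categories, tested against zero per region ×
category with one-sample t-tests under FDR correction (optionally sign-flip
permutation), and classified as consistent or inconsistent with accelerated
ageing by a uniform slope-sign rule: if the trajectory rises throughout the
category, positive deviations are accelerated-consistent (+1); if it falls
throughout, negative ones are (−1); if the turning point falls inside the
category the direction is indeterminate (0).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import as_rng
from .stats import fdr_qvalues
from .trajectories import NormativeTrajectoryModel

__all__ = ["AgeCategory", "DEFAULT_PARTITION", "assign_age_category",
           "compute_deviations", "test_deviations", "accelerated_direction",
           "summarize_deviations"]


@dataclass(frozen=True)
class AgeCategory:
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("age category needs lo < hi")

    @property
    def label(self) -> str:
        return f"{self.lo:g}-{self.hi:g}"


DEFAULT_PARTITION = (AgeCategory(20, 30), AgeCategory(30, 35),
                     AgeCategory(35, 40), AgeCategory(40, 45),
                     AgeCategory(45, 60))


def assign_age_category(age: float, partition=DEFAULT_PARTITION,
                        policy: str = "error"):
    """Map an age to its category: [lo, hi) intervals, last closed [lo, hi].

    ``policy`` for uncovered ages: ``"error"`` raises, ``"drop"`` returns
    None (the subject is excluded with a logged count by callers).
    """
    cats = sorted(partition, key=lambda c: c.lo)
    for i, cat in enumerate(cats):
        last = i == len(cats) - 1
        if cat.lo <= age < cat.hi or (last and age == cat.hi):
            return cat
    if policy == "error":
        raise ValueError(f"age {age} not covered by the partition "
                         f"[{cats[0].lo}, {cats[-1].hi}]")
    return None


def compute_deviations(regional_ms: pd.DataFrame, demographics: pd.DataFrame,
                       model: NormativeTrajectoryModel,
                       partition=DEFAULT_PARTITION,
                       age_policy: str = "drop") -> pd.DataFrame:
    """Per subject × retained region deviation records (long table).

    Ages outside the model's fitted range are flagged (``extrapolated``);
    the quadratic is still evaluated there.  Excluded (non-retained) regions
    are omitted; their count is recorded in ``DataFrame.attrs``.
    """
    demo = demographics.set_index("subject_id")
    common = [s for s in regional_ms.index if s in demo.index]
    if not common:
        raise ValueError("no overlapping subjects between MS table and "
                         "demographics")
    ms = regional_ms.loc[common]
    missing = [r for r in model.regions_ if r not in ms.columns]
    if missing:
        raise ValueError(f"regional MS table lacks model regions: "
                         f"{missing[:5]}")
    ages = demo.loc[common, "age"].to_numpy(float)
    predicted = model.predict(ages)  # n_subjects x n_regions (model order)
    observed = ms[model.regions_].to_numpy(float)
    deviation = observed - predicted
    lo, hi = model.age_range_
    extrapolated = (ages < lo) | (ages > hi)

    cats = []
    for a in ages:
        c = assign_age_category(a, partition, policy=age_policy)
        cats.append(c.label if c is not None else None)
    keep_region = model.retained_
    regions = [r for r, k in zip(model.regions_, keep_region) if k]
    records = pd.DataFrame(deviation[:, keep_region], columns=regions)
    records.insert(0, "subject_id", common)
    long = records.melt(id_vars="subject_id", var_name="region",
                        value_name="deviation")
    meta = pd.DataFrame({"subject_id": common, "age": ages,
                         "age_category": cats,
                         "extrapolated": extrapolated})
    long = long.merge(meta, on="subject_id")
    n_uncovered = int(sum(c is None for c in cats))
    long = long.dropna(subset=["age_category"])
    long.attrs["n_excluded_regions"] = int((~keep_region).sum())
    long.attrs["n_uncovered_subjects"] = n_uncovered
    long.attrs["sign_convention"] = "observed_minus_predicted"
    return long.reset_index(drop=True)


def accelerated_direction(a1: float, a2: float, category: AgeCategory) -> int:
    """+1 / −1 / 0: deviation sign consistent with accelerated ageing.

    The slope of a quadratic is monotone in age, so its sign throughout
    [lo, hi] is fixed by the endpoint signs.  This single rule reproduces
    the four enumerated cases (decreasing → −1 everywhere, increasing → +1,
    convex/concave → the side of the turning point decides; inside → 0).
    Zero slope at an endpoint counts as its limiting interior sign.
    """
    s_lo = a1 + 2.0 * a2 * category.lo
    s_hi = a1 + 2.0 * a2 * category.hi
    # resolve an exactly-zero endpoint slope by the interior behaviour
    if s_lo == 0:
        s_lo = np.sign(s_hi)
    if s_hi == 0:
        s_hi = np.sign(s_lo)
    if s_lo > 0 and s_hi > 0:
        return 1
    if s_lo < 0 and s_hi < 0:
        return -1
    return 0


def test_deviations(records: pd.DataFrame, model: NormativeTrajectoryModel,
                    fdr_q: float = 0.01, n_perm: int = 0,
                    fdr_method: str = "bh", seed: int = 0,
                    partition=DEFAULT_PARTITION) -> pd.DataFrame:
    """One-sample t-tests of mean deviation per region × age category.

    FDR correction runs over regions *within* each category.  Optional
    permutation p-values use subject-level sign flips shared across regions
    (preserving the spatial correlation of deviations).  Zero-variance
    deviations yield an undefined t, reported non-significant and flagged.
    """
    rng = as_rng(seed)
    region_idx = {r: i for i, r in enumerate(model.regions_)}
    cat_by_label = {c.label: c for c in partition}
    out = []
    for label, sub in records.groupby("age_category", sort=True):
        wide = sub.pivot(index="subject_id", columns="region",
                         values="deviation")
        n = len(wide)
        if n < 3:
            continue
        d = wide.to_numpy(float)
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        degenerate = sd <= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
        p = np.where(degenerate, 1.0, p)
        t = np.where(degenerate, 0.0, t)
        q = fdr_qvalues(p, method=fdr_method)
        if n_perm > 0:
            signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
            null_means = (signs @ d) / n
            exceed = (np.abs(null_means) >= np.abs(mean)[None, :]).sum(axis=0)
            perm_p = (1.0 + exceed) / (1.0 + n_perm)
        else:
            perm_p = np.full(mean.size, np.nan)
        cat = cat_by_label[label]
        for j, region in enumerate(wide.columns):
            k = region_idx[region]
            a1 = model.coef_[k, 1]
            a2 = model.coef_[k, 2] if model.coef_.shape[1] > 2 else 0.0
            direction = accelerated_direction(a1, a2, cat)
            significant = bool(q[j] < fdr_q)
            consistent = (bool(np.sign(mean[j]) == direction)
                          if significant and direction != 0 else None)
            out.append({"region": region, "age_category": label,
                        "n": n, "mean_deviation": mean[j],
                        "t": t[j], "p": p[j], "q": q[j],
                        "perm_p": perm_p[j],
                        "degenerate": bool(degenerate[j]),
                        "accelerated_direction": direction,
                        "significant": significant,
                        "accelerated_consistent": consistent})
    result = pd.DataFrame(out)
    result.attrs["fdr_q"] = fdr_q
    result.attrs["fdr_method"] = fdr_method
    result.attrs["n_perm"] = n_perm
    return result


def summarize_deviations(results: pd.DataFrame) -> dict:
    """Cohort summary: significant / accelerated-consistent counts.

    A region counts as significant if any age category flags it; its
    consistency is taken from its significant categories (majority vote,
    indeterminate categories excluded).
    """
    def _summary(frame):
        sig = frame[frame["significant"]]
        det = sig[sig["accelerated_consistent"].notna()]
        n_sig = int(sig["region"].nunique())
        n_con = int(det[det["accelerated_consistent"].astype(bool)]
                    ["region"].nunique())
        pct = (100.0 * n_con / det["region"].nunique()
               if len(det) else None)
        return {"n_significant_regions": n_sig,
                "n_consistent_regions": n_con,
                "pct_consistent": pct,
                "indeterminate_regions": sorted(
                    sig.loc[sig["accelerated_direction"] == 0,
                            "region"].unique().tolist())}

    summary = {"overall": _summary(results), "by_category": {}}
    for label, sub in results.groupby("age_category"):
        summary["by_category"][label] = _summary(sub)
    return summary
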