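"""Morphometric similarity networks from regional feature tables.

For each subject the seven features are z-scored across regions, regions are
pairwise Pearson-correlated over the seven features, and the resulting
square similarity matrix is column-averaged (diagonal excluded) into one
regional mean MS value per region — the region's weighted degree divided by
(N − 1), i.e. its "hubness".
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import FEATURES, as_rng

__all__ = ["zscore_features", "compute_ms_matrix", "regional_mean_ms",
           "subject_regional_ms", "cohort_regional_ms", "cohort_mean_map",
           "map_correlation"]

FEATURE_NAMES = [f[0] for f in FEATURES]


class DegenerateFeatureError(ValueError):
    """A feature has zero variance across regions for a subject."""


def _subject_block(table: pd.DataFrame, subject) -> pd.DataFrame:
    block = table.loc[table["subject_id"] == subject]
    if block.empty:
        raise KeyError(f"subject {subject!r} not present in feature table")
    dup = block["region"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate region rows for subject {subject!r}: "
                         f"{block.loc[dup, 'region'].tolist()[:5]}")
    return block.set_index("region")[FEATURE_NAMES]


def zscore_features(table: pd.DataFrame, subject) -> pd.DataFrame:
    """Z-score each feature across regions within one subject.

    Uses the sample SD (ddof=1).  A feature constant across regions is a
    degenerate input and raises :class:`DegenerateFeatureError` naming it.
    """
    block = _subject_block(table, subject)
    if len(block) < 2:
        raise ValueError("need >= 2 regions to z-score across regions")
    values = block.to_numpy(float)
    if not np.isfinite(values).all():
        raise ValueError(f"non-finite feature values for subject {subject!r}")
    sd = values.std(axis=0, ddof=1)
    zero = sd <= 0
    if zero.any():
        bad = [n for n, z in zip(FEATURE_NAMES, zero) if z]
        raise DegenerateFeatureError(
            f"feature(s) {bad} constant across regions for subject {subject!r}")
    z = (values - values.mean(axis=0)) / sd
    return pd.DataFrame(z, index=block.index, columns=FEATURE_NAMES)


def compute_ms_matrix(normalized: pd.DataFrame) -> pd.DataFrame:
    """Pearson-correlate regions over their z-scored 7-feature profiles.

    Regions whose profile has zero variance across features cannot be
    correlated; their rows/columns are set to NaN (flagged missing) and are
    excluded by downstream column means.
    """
    z = normalized.to_numpy(float)
    profile_sd = z.std(axis=1)
    valid = profile_sd > 0
    ms = np.full((z.shape[0], z.shape[0]), np.nan)
    if valid.sum() >= 2:
        sub = np.corrcoef(z[valid])
        ms[np.ix_(valid, valid)] = sub
    np.fill_diagonal(ms, 1.0)
    return pd.DataFrame(ms, index=normalized.index, columns=normalized.index)


def regional_mean_ms(ms_matrix: pd.DataFrame) -> pd.Series:
    """Column mean of the MS matrix excluding the diagonal.

    Including the self-correlation of 1 would inflate every value by ~1/N;
    exclusion matches the weighted-degree reading (degree / (N − 1)).
    """
    m = ms_matrix.to_numpy(float).copy()
    if m.shape[0] != m.shape[1]:
        raise ValueError("MS matrix must be square")
    np.fill_diagonal(m, np.nan)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(m, axis=0)
    return pd.Series(means, index=ms_matrix.columns, name="regional_ms")


def subject_regional_ms(table: pd.DataFrame, subject) -> pd.Series:
    """Feature table -> regional mean MS for one subject."""
    return regional_mean_ms(compute_ms_matrix(zscore_features(table, subject)))


def cohort_regional_ms(table: pd.DataFrame) -> pd.DataFrame:
    """Feature table -> subject × region regional-MS table."""
    subjects = table["subject_id"].unique()
    rows = [subject_regional_ms(table, s) for s in subjects]
    out = pd.DataFrame(rows, index=pd.Index(subjects, name="subject_id"))
    return out


def cohort_mean_map(regional_ms: pd.DataFrame) -> pd.Series:
    """Per-region mean over subjects (the cohort's cortical MS map)."""
    if len(regional_ms) == 0:
        raise ValueError("empty cohort")
    out = regional_ms.mean(axis=0)
    out.name = "mean_ms"
    out.attrs["n_subjects"] = len(regional_ms)
    return out


def map_correlation(map_a: pd.Series, map_b: pd.Series,
                    n_perm: int = 0, seed: int = 0,
                    alternative: str = "two-sided") -> dict:
    """Pearson correlation between two regional maps over matched regions.

    With ``n_perm > 0`` a permutation p-value is computed by shuffling region
    labels of one map (add-one estimator, two-sided by default).
    """
    if set(map_a.index) != set(map_b.index):
        raise ValueError("maps are defined on different region sets")
    if len(map_a) < 3:
        raise ValueError("need at least 3 regions")
    b = map_b.reindex(map_a.index).to_numpy(float)
    a = map_a.to_numpy(float)
    r = float(np.corrcoef(a, b)[0, 1])
    result = {"r": r, "n_regions": len(a)}
    if n_perm > 0:
        rng = as_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = np.corrcoef(a, rng.permutation(b))[0, 1]
        if alternative == "two-sided":
            exceed = np.sum(np.abs(null) >= abs(r))
        elif alternative == "greater":
            exceed = np.sum(null >= r)
        else:
            exceed = np.sum(null <= r)
        result["p_perm"] = float((1 + exceed) / (1 + n_perm))
        result["alternative"] = alternative
    return result
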