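"""Synthetic cohort generation with known ground-truth ageing trajectories.

Two generation modes share one trajectory language (per-region quadratic
age -> regional-MS curves):

* **MS level** — regional mean morphometric similarity is written directly as
  ``a0 + a1*age + a2*age**2 + noise`` per subject and region.
* **Feature level** — seven raw morphometric features per region are
  constructed such that the regional mean MS *computed from them* (z-score,
  Pearson, column mean) tracks the same trajectories.

The feature-level construction places each region's 7-feature profile at a
controlled alignment to a fixed zero-mean template direction ``u``:

    x_r = alpha_r * u + c_r * e_r,        e_r ⟂ span{1, u},  |e_r| = 1

With unit-scale alignment ``t_r = alpha_r / sqrt(alpha_r² + c_r²)`` the MS
matrix entry for regions r, q is ``t_r t_q`` up to O(1/sqrt(N)) noise, so the
regional mean MS is ``t_r (S − t_r)/(N−1)`` with ``S = Σ t``.  Target MS
values ``m_r`` are hit by solving that fixed point for ``t``.  Row scales
``rho_r = exp(−beta t_r)`` with ``Σ t_r rho_r = 0`` keep the per-feature
across-region centering (applied later by the network stage) from removing
the template component.  The solvable envelope requires targets balanced in
sign with ``max|m| ≲ sqrt((N·mean(m)+1)/(N−1))``; the default trajectories
are designed inside it.

"Aged" patient profiles are injected by evaluating a subject's trajectory at
``age + delta_years`` in a configurable set of affected regions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .parcellation import Parcellation

__all__ = [
    "CohortSpec", "TrajectorySpec", "AgedInjectionSpec", "PALSpec",
    "default_trajectories", "sample_cohort", "generate_regional_ms",
    "generate_feature_table", "generate_pal", "trajectory_frame",
    "decreasing_regions", "FEATURES",
]

#: the seven morphometric features and plausible raw location/scale (units in
#: the docstring of :func:`generate_feature_table`)
FEATURES = (
    ("grey_matter_volume", 4800.0, 480.0),
    ("surface_area", 1500.0, 150.0),
    ("cortical_thickness", 2.60, 0.26),
    ("mean_curvature", 0.130, 0.013),
    ("gaussian_curvature", 0.025, 0.0025),
    ("folding_index", 12.0, 1.2),
    ("intrinsic_curvature_index", 3.0, 0.3),
)

GROUPS = ("normative", "control", "patient")


def as_rng(seed) -> np.random.Generator:
    """Accept an int seed or a Generator; never touch global state."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# specification types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Demographic specification for one simulated cohort."""

    n_subjects: int
    age_range: tuple[float, float] = (20.0, 80.0)
    sex_ratio: float = 0.5          # fraction female
    group: str = "normative"
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range lo must be < hi")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")


@dataclass(frozen=True)
class TrajectorySpec:
    """Quadratic age trajectory of one region's mean MS.

    ``value(age) = a0 + a1*age + a2*age**2``; slope is ``a1 + 2*a2*age``.
    ``noise_sd`` is the SD of the additive subject-level perturbation in MS
    units (applied in both generation modes).
    """

    region: str
    a0: float
    a1: float
    a2: float
    noise_sd: float = 0.015

    def __post_init__(self):
        for name in ("a0", "a1", "a2", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def value(self, age):
        age = np.asarray(age, dtype=float)
        return self.a0 + self.a1 * age + self.a2 * age ** 2

    def slope(self, age):
        return self.a1 + 2.0 * self.a2 * np.asarray(age, dtype=float)


@dataclass(frozen=True)
class AgedInjectionSpec:
    """Shift of trajectory-evaluation age for patient subjects."""

    delta_years: float
    affected_regions: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not np.isfinite(self.delta_years):
            raise ValueError("delta_years must be finite")


@dataclass(frozen=True)
class PALSpec:
    """Generative model of paired-associates-learning total errors.

    ``total_errors = b0 + b_age*age + b_group*[patient] + noise``, truncated
    at zero and rounded (errors are counts).  ``group_betas`` optionally maps
    an age-category label to a category-specific group effect, overriding
    ``beta_group`` for calibration experiments.
    """

    beta_intercept: float = 12.0
    beta_age: float = 0.35           # errors per year
    beta_group: float = 12.0         # extra errors for patients
    noise_sd: float = 10.0           # error counts
    group_betas: tuple = ()          # ((lo, hi, beta), ...) optional

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for v in (self.beta_intercept, self.beta_age, self.beta_group):
            if not np.isfinite(v):
                raise ValueError("PAL betas must be finite")


# ---------------------------------------------------------------------------
# default ground-truth trajectories
# ---------------------------------------------------------------------------

#: slope ranges (MS/year) and age-40 value ranges (MS) per trajectory class.
#: Values are modest (|MS| <= ~0.1) so the feature-level construction stays
#: inside its solvable envelope; decreasing-class slopes are strong enough
#: that a +10-year injection is detectable at realistic category sizes.
_CLASS_PARAMS = {
    "increasing": dict(s27=(0.0015, 0.0028), s60=(0.0015, 0.0028),
                       v40=(-0.050, -0.015)),
    "decreasing": dict(s27=(-0.0028, -0.0018), s60=(-0.0028, -0.0018),
                       v40=(0.015, 0.050)),
    "convex": dict(s27=(0.0008, 0.0018), s60=(-0.0018, -0.0008),
                   v40=(0.010, 0.060)),
    "concave": dict(s27=(-0.0018, -0.0008), s60=(0.0008, 0.0018),
                    v40=(0.000, 0.050)),
}

DEFAULT_CLASS_COUNTS = {"increasing": 121, "decreasing": 119,
                        "convex": 57, "concave": 63}


def default_trajectories(parcellation: Parcellation | None = None,
                         seed: int = 0,
                         class_counts: dict[str, int] | None = None,
                         n_noise: int = 0,
                         noise_sd: float = 0.015,
                         early: float = 27.0, late: float = 60.0,
                         ) -> list[TrajectorySpec]:
    """Draw a ground-truth trajectory per region across the four shape classes.

    ``n_noise`` regions (sampled without replacement) are replaced by flat
    pure-noise trajectories (``a1 = a2 = 0``), exercising the adjusted-R²
    exclusion rule downstream.  Class labels can be recovered from the
    returned specs via :func:`msageing.trajectories.classify_trajectory`.
    """
    parcellation = parcellation or Parcellation()
    counts = dict(class_counts or DEFAULT_CLASS_COUNTS)
    n = parcellation.n_regions
    if sum(counts.values()) != n:
        # rescale proportionally to the parcellation size
        total = sum(counts.values())
        scaled = {k: max(1, int(round(v * n / total))) for k, v in counts.items()}
        while sum(scaled.values()) != n:
            k = max(scaled, key=scaled.get)
            scaled[k] += n - sum(scaled.values())
            scaled[k] = max(1, scaled[k])
        counts = scaled
    rng = as_rng(seed)
    classes = [c for c, k in counts.items() for _ in range(k)]
    rng.shuffle(classes)
    span = 2.0 * (late - early)
    specs = []
    for region, cls in zip(parcellation.labels, classes):
        p = _CLASS_PARAMS[cls]
        s27 = rng.uniform(*p["s27"])
        s60 = rng.uniform(*p["s60"])
        v40 = rng.uniform(*p["v40"])
        a2 = (s60 - s27) / span
        a1 = s27 - 2.0 * a2 * early
        a0 = v40 - a1 * 40.0 - a2 * 1600.0
        specs.append(TrajectorySpec(region, a0, a1, a2, noise_sd))
    if n_noise > 0:
        idx = rng.choice(n, size=min(n_noise, n), replace=False)
        base = float(np.mean([s.a0 + s.a1 * 40 + s.a2 * 1600 for s in specs]))
        for i in idx:
            specs[i] = TrajectorySpec(specs[i].region, base, 0.0, 0.0, noise_sd)
    return specs


def trajectory_frame(trajectories: list[TrajectorySpec]) -> pd.DataFrame:
    """Tabular view of trajectory specs (region-indexed)."""
    return pd.DataFrame(
        {"region": [t.region for t in trajectories],
         "a0": [t.a0 for t in trajectories],
         "a1": [t.a1 for t in trajectories],
         "a2": [t.a2 for t in trajectories],
         "noise_sd": [t.noise_sd for t in trajectories]},
    ).set_index("region")


def decreasing_regions(trajectories: list[TrajectorySpec],
                       early: float = 27.0, late: float = 60.0) -> frozenset:
    """Regions whose generating trajectory declines at both reference ages."""
    return frozenset(t.region for t in trajectories
                     if t.slope(early) < 0 and t.slope(late) < 0)


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def sample_cohort(spec: CohortSpec, id_prefix: str | None = None) -> pd.DataFrame:
    """Sample a demographics table: subject_id, age, sex, group.

    Ages are uniform on ``age_range`` (the normative source gives no age
    density, so uniform is the default and the density is configurable by
    resampling the column).
    """
    rng = as_rng(spec.seed)
    prefix = id_prefix if id_prefix is not None else spec.group[:3]
    ids = [f"{prefix}-{i + 1:04d}" for i in range(spec.n_subjects)]
    ages = rng.uniform(*spec.age_range, size=spec.n_subjects)
    sex = np.where(rng.uniform(size=spec.n_subjects) < spec.sex_ratio, "F", "M")
    return pd.DataFrame({"subject_id": ids, "age": ages, "sex": sex,
                         "group": spec.group})


def _effective_ages(demographics: pd.DataFrame, regions: list[str],
                    injection: AgedInjectionSpec | None) -> np.ndarray:
    """Per subject × region evaluation age, shifted for injected patients."""
    ages = demographics["age"].to_numpy(float)[:, None]
    eff = np.repeat(ages, len(regions), axis=1)
    if injection is not None and injection.delta_years != 0:
        is_patient = (demographics["group"] == "patient").to_numpy()
        col = np.array([r in injection.affected_regions for r in regions])
        eff[np.ix_(is_patient, col)] += injection.delta_years
    return eff


def _check_trajectories(trajectories, regions):
    have = {t.region for t in trajectories}
    missing = [r for r in regions if r not in have]
    if missing:
        raise ValueError(f"missing TrajectorySpec for regions: {missing[:5]}")


def generate_regional_ms(demographics: pd.DataFrame,
                         trajectories: list[TrajectorySpec],
                         injection: AgedInjectionSpec | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Write regional mean MS directly from the trajectories (MS-level mode).

    Returns a subject × region table (index = subject_id).
    """
    regions = [t.region for t in trajectories]
    _check_trajectories(trajectories, regions)
    if injection is not None:
        unknown = set(injection.affected_regions) - set(regions)
        if unknown:
            raise ValueError(f"injection regions outside parcellation: "
                             f"{sorted(unknown)[:5]}")
    rng = as_rng(seed)
    eff = _effective_ages(demographics, regions, injection)
    a0 = np.array([t.a0 for t in trajectories])
    a1 = np.array([t.a1 for t in trajectories])
    a2 = np.array([t.a2 for t in trajectories])
    sd = np.array([t.noise_sd for t in trajectories])
    values = a0 + a1 * eff + a2 * eff ** 2
    if sd.any():
        values = values + rng.standard_normal(values.shape) * sd
    return pd.DataFrame(values, index=pd.Index(demographics["subject_id"],
                                               name="subject_id"),
                        columns=regions)


# ---------------------------------------------------------------------------
# feature-level construction
# ---------------------------------------------------------------------------

# fixed zero-mean template over the 7 features; six equal-magnitude entries
# keep the per-feature standardization near-isotropic on the template span
_TEMPLATE = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0, 0.0])
_TEMPLATE /= np.linalg.norm(_TEMPLATE)
_ONES7 = np.ones(7) / np.sqrt(7.0)


def _solve_alignments(m: np.ndarray, n_iter: int = 250,
                      clip: float = 0.95) -> np.ndarray:
    """Solve m_r = t_r (S − t_r)/(N−1) for the alignment vector t (damped)."""
    n = m.size
    t = np.sign(m) * np.sqrt(np.abs(m))
    for _ in range(n_iter):
        s = t.sum()
        new = np.clip(m * (n - 1) / np.clip(s - t, 1e-9, None), -clip, clip)
        t = 0.5 * t + 0.5 * new
    return t


def _row_scales(t: np.ndarray) -> np.ndarray:
    """Positive row scales rho = exp(−beta t) with Σ t·rho = 0.

    Falls back to unit scales when the loadings are one-signed (no root); the
    resulting centering loss only attenuates the realized similarity scale.
    """
    def f(b):
        return float(np.sum(t * np.exp(np.clip(-b * t, -30.0, 30.0))))

    hi = 1.0
    while f(hi) > 0 and hi < 256:
        hi *= 2
    lo = -1.0
    while f(lo) < 0 and lo > -256:
        lo *= 2
    if f(hi) > 0 or f(lo) < 0:
        return np.ones_like(t)
    beta = brentq(f, lo, hi)
    return np.exp(np.clip(-beta * t, -30.0, 30.0))


def _subject_profiles(m_target: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One subject's region × 7 standardized profile block hitting m_target."""
    t = _solve_alignments(m_target)
    rho = _row_scales(t)
    alpha = t * rho
    c = rho * np.sqrt(1.0 - t ** 2)
    e = rng.standard_normal((m_target.size, 7))
    e -= (e @ _ONES7)[:, None] * _ONES7[None, :]
    e -= (e @ _TEMPLATE)[:, None] * _TEMPLATE[None, :]
    norms = np.linalg.norm(e, axis=1, keepdims=True)
    e /= np.where(norms > 0, norms, 1.0)
    return alpha[:, None] * _TEMPLATE[None, :] + c[:, None] * e


def generate_feature_table(demographics: pd.DataFrame,
                           trajectories: list[TrajectorySpec],
                           injection: AgedInjectionSpec | None = None,
                           seed: int = 0) -> pd.DataFrame:
    """Generate the 7-feature raw table (wide: subject_id, region, features).

    Raw scales: grey-matter volume (mm³), surface area (mm²), cortical
    thickness (mm), mean curvature (mm⁻¹), Gaussian curvature (mm⁻²),
    folding index and intrinsic curvature index (dimensionless).  Volume,
    area and thickness are strictly positive by construction (the latent
    profile is bounded, |z| < 2, and scales are ≤ 10% of locations).
    """
    regions = [t.region for t in trajectories]
    if len(regions) < 2:
        raise ValueError("at least 2 regions are required "
                         "(similarity is undefined otherwise)")
    _check_trajectories(trajectories, regions)
    rng = as_rng(seed)
    eff = _effective_ages(demographics, regions, injection)
    a0 = np.array([t.a0 for t in trajectories])
    a1 = np.array([t.a1 for t in trajectories])
    a2 = np.array([t.a2 for t in trajectories])
    sd = np.array([t.noise_sd for t in trajectories])
    targets = a0 + a1 * eff + a2 * eff ** 2
    if sd.any():
        targets = targets + rng.standard_normal(targets.shape) * sd

    locs = np.array([f[1] for f in FEATURES])
    scales = np.array([f[2] for f in FEATURES])
    frames = []
    for i, sid in enumerate(demographics["subject_id"]):
        z = _subject_profiles(targets[i], rng)
        raw = locs[None, :] + scales[None, :] * z
        block = pd.DataFrame(raw, columns=[f[0] for f in FEATURES])
        block.insert(0, "region", regions)
        block.insert(0, "subject_id", sid)
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# behavioural scores
# ---------------------------------------------------------------------------

def generate_pal(demographics: pd.DataFrame, spec: PALSpec,
                 seed: int = 0) -> pd.DataFrame:
    """Generate PAL total errors and first-trial memory score.

    Total errors follow the linear model in :class:`PALSpec`, truncated at
    zero and rounded (counts).  The first-trial memory score is a decreasing
    function of total errors on the 0–24 scale of the touchscreen task.
    """
    rng = as_rng(seed)
    age = demographics["age"].to_numpy(float)
    is_patient = (demographics["group"] == "patient").to_numpy()
    beta_g = np.full(age.size, float(spec.beta_group))
    for lo, hi, beta in spec.group_betas:
        sel = (age >= lo) & (age < hi)
        beta_g[sel] = beta
    errors = (spec.beta_intercept + spec.beta_age * age
              + beta_g * is_patient)
    if spec.noise_sd > 0:
        errors = errors + rng.standard_normal(age.size) * spec.noise_sd
    errors = np.maximum(np.round(errors), 0).astype(int)
    ftms = np.maximum(24 - np.round(0.45 * errors), 0).astype(int)
    return pd.DataFrame({"subject_id": demographics["subject_id"],
                         "pal_total_errors": errors,
                         "pal_first_trial_memory": ftms})
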