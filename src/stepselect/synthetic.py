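"""Synthetic stroke-cohort generator with planted informative features.

Emulates the statistical structure the downstream analysis assumes: a
participant-by-feature table of mixed continuous / ordinal / categorical
clinical variables, a latent linear model on the steps-per-day scale,

    aspd_true = base + sum_j coef_j * z_j + Normal(0, noise_sd),  floored at 0,

where ``z_j`` is the standardized j-th feature, and a short wearable
recording per participant whose valid-day average is a noisy, unbiased
realization of ``aspd_true``. Because the latent model lives on the step
scale (not on a label), both binary thresholds (2500 and 5500 steps/day)
can be applied to one cohort, exactly as the analysis does.

The ``study_spec`` helper calibrates the intercept and total latent spread
so that the below-2500 and below-5500 prevalences match the class
distributions observed in a real chronic-stroke cohort of n=268
(about 21.6% and 69.0%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import FEATURE_KINDS, FeatureTable, compute_aspd

__all__ = [
    "FeatureSpec",
    "CorrelationBlock",
    "SyntheticSpec",
    "SyntheticCohort",
    "generate_cohort",
    "expected_prevalence",
    "study_spec",
    "write_fixture",
    "read_fixture",
]

# prevalences the default cohort is calibrated to (58/268 and 185/268)
TARGET_PREV_2500 = 58 / 268
TARGET_PREV_5500 = 185 / 268


@dataclass(frozen=True)
class FeatureSpec:
    """One feature: name, kind, and (for non-continuous kinds) its levels."""

    name: str
    kind: str = "continuous"
    levels: int | None = None
    level_probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown kind {self.kind!r} for feature {self.name!r}")
        if self.kind != "continuous":
            if self.levels is None or self.levels < 2:
                raise ValueError(f"feature {self.name!r} needs >= 2 levels")
            if self.level_probs is not None and len(self.level_probs) != self.levels:
                raise ValueError(f"level_probs length mismatch for {self.name!r}")


@dataclass(frozen=True)
class CorrelationBlock:
    """Equicorrelated block among continuous features (Gaussian copula)."""

    features: tuple[str, ...]
    rho: float

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"rho must be in (-1,1), got {self.rho}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic cohort; same spec + seed => same cohort."""

    n_participants: int
    feature_specs: tuple[FeatureSpec, ...]
    true_coefficients: dict[str, float] = field(default_factory=dict)
    correlation: tuple[CorrelationBlock, ...] = ()
    step_mean_base: float = 4000.0
    step_noise_sd: float = 2000.0
    wear_days: int = 7
    invalid_day_rate: float = 0.1
    day_noise_sd: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 10:
            raise ValueError(f"need n >= 10 participants, got {self.n_participants}")
        if not self.feature_specs:
            raise ValueError("feature_specs must not be empty")
        names = [f.name for f in self.feature_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")
        unknown = set(self.true_coefficients) - set(names)
        if unknown:
            raise ValueError(f"coefficients for unknown features: {sorted(unknown)}")
        if self.step_noise_sd < 0:
            raise ValueError("step_noise_sd must be >= 0")
        if not 0.0 <= self.invalid_day_rate < 1.0:
            raise ValueError("invalid_day_rate must be in [0,1)")
        if self.wear_days < 3:
            raise ValueError("wear_days must be >= 3")
        cont = {f.name for f in self.feature_specs if f.kind == "continuous"}
        for block in self.correlation:
            if not set(block.features) <= cont:
                raise ValueError("correlation blocks may only cover continuous features")

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.feature_specs]


@dataclass
class SyntheticCohort:
    """Generated cohort: features, daily step records, true latent ASPD."""

    features: FeatureTable
    daily_steps: dict[object, list[tuple[int, int, bool]]]
    aspd_true: pd.Series
    spec: SyntheticSpec

    @property
    def aspd_observed(self) -> pd.Series:
        """ASPD as the analysis would compute it, from the valid days."""
        vals = {pid: compute_aspd(rec) for pid, rec in self.daily_steps.items()}
        return pd.Series(vals, name="aspd").loc[self.features.ids]


def _draw_features(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_participants
    cols: dict[str, np.ndarray] = {}
    in_block = {f for b in spec.correlation for f in b.features}
    for fs in spec.feature_specs:
        if fs.kind == "continuous":
            if fs.name not in in_block:
                cols[fs.name] = rng.normal(size=n)
        else:
            probs = fs.level_probs
            cols[fs.name] = rng.choice(fs.levels, size=n, p=probs).astype(float)
    for block in spec.correlation:
        k = len(block.features)
        cov = np.full((k, k), block.rho)
        np.fill_diagonal(cov, 1.0)
        draws = rng.multivariate_normal(np.zeros(k), cov, size=n)
        for j, name in enumerate(block.features):
            cols[name] = draws[:, j]
    ids = [f"p{i:04d}" for i in range(n)]
    data = pd.DataFrame({f.name: cols[f.name] for f in spec.feature_specs}, index=ids)
    data.index.name = "id"
    return data


def _standardize(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    if sd == 0:
        return np.zeros_like(col)
    return (col - col.mean()) / sd


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Draw one cohort from ``spec``; bit-identical for identical spec + seed."""
    ss = np.random.SeedSequence(spec.seed)
    rng_feat, rng_latent, rng_steps = (np.random.default_rng(s) for s in ss.spawn(3))

    data = _draw_features(spec, rng_feat)
    latent = np.full(spec.n_participants, spec.step_mean_base, dtype=float)
    for name, coef in spec.true_coefficients.items():
        latent += coef * _standardize(data[name].to_numpy())
    latent += rng_latent.normal(0.0, spec.step_noise_sd, size=spec.n_participants)
    aspd_true = pd.Series(np.maximum(latent, 0.0), index=data.index, name="aspd_true")

    daily: dict[object, list[tuple[int, int, bool]]] = {}
    for pid, mu in aspd_true.items():
        valid = rng_steps.random(spec.wear_days) >= spec.invalid_day_rate
        if valid.sum() < 3:  # guarantee the 3-valid-day minimum of a usable record
            valid[:3] = True
        records = []
        for day in range(spec.wear_days):
            if valid[day]:
                count = max(0, int(round(rng_steps.normal(mu, spec.day_noise_sd))))
            else:
                count = int(rng_steps.integers(0, 1000))  # junk; must be ignored
            records.append((day + 1, count, bool(valid[day])))
        daily[pid] = records

    kinds = {f.name: f.kind for f in spec.feature_specs}
    return SyntheticCohort(
        features=FeatureTable(data=data, kinds=kinds),
        daily_steps=daily,
        aspd_true=aspd_true,
        spec=spec,
    )


def _total_latent_sd(spec: SyntheticSpec) -> float:
    coef_var = sum(c * c for c in spec.true_coefficients.values())
    return float(np.sqrt(coef_var + spec.step_noise_sd**2))


def expected_prevalence(spec: SyntheticSpec, threshold: float) -> float:
    """Analytic below-threshold prevalence under the latent normal model.

    Treats the standardized-feature contribution as an extra independent
    normal component (accurate when signals sit on continuous features).
    """
    return float(stats.norm.cdf((threshold - spec.step_mean_base) / _total_latent_sd(spec)))


# Feature roster loosely mirroring a chronic-stroke assessment battery:
# walking capacity, balance, mood, deprivation, comorbidity, demographics.
_STUDY_FEATURES: tuple[FeatureSpec, ...] = (
    FeatureSpec("six_minute_walk"),
    FeatureSpec("speed_modulation"),
    FeatureSpec("self_selected_speed"),
    FeatureSpec("fastest_speed"),
    FeatureSpec("balance_confidence"),
    FeatureSpec("depression_score"),
    FeatureSpec("deprivation_index"),
    FeatureSpec("comorbidity_index"),
    FeatureSpec("time_since_stroke"),
    FeatureSpec("age"),
    FeatureSpec("bmi"),
    FeatureSpec("grip_strength"),
    FeatureSpec("cognition_score"),
    FeatureSpec("fatigue_score"),
    FeatureSpec("pain_score"),
    FeatureSpec("readiness_stage", "ordinal", 5),
    FeatureSpec("readiness_relapse", "ordinal", 5),
    FeatureSpec("education_years", "ordinal", 8),
    FeatureSpec("assistive_device", "categorical", 3),
    FeatureSpec("sex", "categorical", 2),
    FeatureSpec("stroke_side", "categorical", 2),
    FeatureSpec("stroke_type", "categorical", 2),
    FeatureSpec("employment", "categorical", 3),
    FeatureSpec("lives_alone", "categorical", 2),
    FeatureSpec("exercise_habit", "ordinal", 4),
)


def study_spec(
    seed: int = 0,
    n_participants: int = 268,
    signal_features: Sequence[str] = ("six_minute_walk", "speed_modulation"),
    effect_to_noise: float = 1.25,
    wear_days: int = 7,
    invalid_day_rate: float = 0.1,
) -> SyntheticSpec:
    """A 25-feature cohort spec calibrated to the study's class distributions.

    The intercept and total latent spread are solved analytically so that
    P(ASPD < 2500) ~= 21.6% and P(ASPD < 5500) ~= 69.0%, whatever signals are
    planted: the planted effects and the residual noise always combine to the
    same total spread. Each planted coefficient equals ``effect_to_noise``
    residual noise SDs per standardized unit (a strong effect at the default
    1.25). ``signal_features`` may be empty for a pure-noise (null) cohort;
    only continuous features can carry signal.
    """
    names = [f.name for f in _STUDY_FEATURES]
    for s in signal_features:
        if s not in names:
            raise ValueError(f"unknown signal feature {s!r}")
    z_lo = stats.norm.ppf(TARGET_PREV_2500)
    z_hi = stats.norm.ppf(TARGET_PREV_5500)
    total_sd = (5500.0 - 2500.0) / (z_hi - z_lo)
    base = 2500.0 - z_lo * total_sd
    k = len(signal_features)
    r = effect_to_noise
    noise_sd = total_sd / np.sqrt(1.0 + k * r * r)
    coef = r * noise_sd
    return SyntheticSpec(
        n_participants=n_participants,
        feature_specs=_STUDY_FEATURES,
        true_coefficients={s: coef for s in signal_features},
        step_mean_base=base,
        step_noise_sd=noise_sd,
        wear_days=wear_days,
        invalid_day_rate=invalid_day_rate,
        seed=seed,
    )


def write_fixture(cohort: SyntheticCohort, path) -> Path:
    """Write the cohort as a CSV (id, features, aspd) plus a JSON sidecar.

    The ``aspd`` column holds the observed valid-day average. The sidecar
    (same stem, ``.json``) records seed and true coefficients so tests can
    recover the generating truth. Round-trips losslessly with
    ``read_fixture``.
    """
    path = Path(path)
    out = cohort.features.data.copy()
    out["aspd"] = cohort.aspd_observed
    out.to_csv(path, index=True)
    sidecar = {
        "seed": cohort.spec.seed,
        "n_participants": cohort.spec.n_participants,
        "true_coefficients": cohort.spec.true_coefficients,
        "step_mean_base": cohort.spec.step_mean_base,
        "step_noise_sd": cohort.spec.step_noise_sd,
        "kinds": dict(cohort.features.kinds),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_fixture(path) -> tuple[FeatureTable, pd.Series]:
    """Read a fixture CSV back into a FeatureTable and its ASPD column."""
    path = Path(path)
    df = pd.read_csv(path, index_col="id")
    if "aspd" not in df.columns:
        raise ValueError(f"{path} has no 'aspd' column")
    aspd = df.pop("aspd")
    kinds: dict[str, str] = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        kinds = json.loads(sidecar.read_text()).get("kinds", {})
        kinds = {k: v for k, v in kinds.items() if k in df.columns}
    return FeatureTable(data=df, kinds=kinds), aspd
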