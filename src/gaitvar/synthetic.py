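"""Synthetic walking trials and cohorts with the structure the analysis assumes.

The study data (19 older adults, two walks of SPPB Test 2 each, recorded as
17-keypoint pose streams) are not publicly deposited, so this module
generates statistically analogous stand-ins:

* :func:`simulate_walk_trial` — a forward walk in pixel units where each
  foot advances by Gaussian step increments with an optional linear trend
  (stride lengthening/shortening over the trial), optional phase-offset
  sinusoidal gait-cycle modulation, left/right asymmetry, and keypoint
  confidence dropout.  The frame-to-frame Euclidean displacement of a foot
  equals its step increment by construction, so the generative step variance
  is also the displacement variance the pipeline should recover.
* :func:`simulate_cohort` — per-subject demographics, two simulated trials,
  and SPPB-style durations linearly coupled to the composite gait index:
  ``duration = intercept + coupling_beta * var_mean + N(0, noise_sd)``,
  split over the two trials with trial 1 slower (an adaptation effect).
  Ordinal 0-4 scores follow from durations through a threshold rule.

Everything is deterministic given the config seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path


import numpy as np
import pandas as pd

from . import features as _features
from .errors import ConfigError
from .pose_io import (
    LEFT_FOOT,
    N_KEYPOINTS,
    RIGHT_FOOT,
    PoseSequence,
    write_keypoint_json,
)

__all__ = [
    "WalkSimConfig",
    "CohortSimConfig",
    "ScoreRule",
    "CohortSimResult",
    "simulate_walk_trial",
    "simulate_cohort",
    "write_keypoint_json",
    "write_cohort",
    "expected_duration_correlation",
    "noise_sd_for_correlation",
]

#: cohort CSV header, fixed interface
COHORT_COLUMNS = (
    "subject_id",
    "age",
    "gender",
    "height_cm",
    "weight_kg",
    "score2_1",
    "score2_2",
    "score2",
    "duration1",
    "duration2",
    "duration",
)


@dataclass(frozen=True)
class WalkSimConfig:
    """Generative parameters for one walking trial (pixel units per frame).

    ``step_mean``/``step_sd`` set the per-frame foot displacement mean and
    noise SD; ``trend`` adds a linear drift in step length (pixels/frame,
    may be negative) emulating the gradual stride lengthening or shortening
    seen across subjects; ``lr_asymmetry`` multiplies the right foot's step
    mean and SD; ``cycle_amplitude``/``cycle_period`` add a phase-offset
    sinusoidal gait-cycle modulation of step size (amplitude 0 disables it,
    keeping the zero-noise trial exactly constant-step); ``dropout_rate`` is
    the probability a frame's foot keypoint confidence falls below the usual
    0.3 detection threshold.
    """

    n_frames: int = 300
    step_mean: float = 8.0
    step_sd: float = 2.0
    trend: float = 0.0
    lr_asymmetry: float = 1.0
    dropout_rate: float = 0.0
    cycle_amplitude: float = 0.0
    cycle_period: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if int(self.n_frames) < 2:
            raise ConfigError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.step_mean < 0:
            raise ConfigError(f"step_mean must be >= 0, got {self.step_mean}")
        if self.step_sd < 0:
            raise ConfigError(f"step_sd must be >= 0, got {self.step_sd}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError(
                f"dropout_rate must lie in [0, 1), got {self.dropout_rate}"
            )
        if self.lr_asymmetry < 0:
            raise ConfigError(
                f"lr_asymmetry must be >= 0, got {self.lr_asymmetry}"
            )
        if self.cycle_period <= 0:
            raise ConfigError(
                f"cycle_period must be > 0, got {self.cycle_period}"
            )


@dataclass(frozen=True)
class ScoreRule:
    """Map a walk duration (seconds) to an SPPB-style ordinal score 0-4.

    Faster walks score higher: 4 below the first threshold, then 3, 2, and
    1 beyond the last; 0 is reserved for an absent/failed walk.  Defaults
    are per-trial thresholds chosen so simulated cohorts span the scale.
    """

    thresholds: tuple[float, float, float] = (2.0, 3.0, 4.5)

    def score(self, duration: float) -> int:
        t4, t3, t2 = self.thresholds
        if not math.isfinite(duration):
            return 0
        if duration < t4:
            return 4
        if duration < t3:
            return 3
        if duration < t2:
            return 2
        return 1


@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort-level generative parameters.

    Defaults mirror the study conditions: 19 subjects, ~79% male, ages 60+.
    ``coupling_beta`` (seconds per pixel^2) is the slope of the linear
    var_mean -> total-duration link; negative values reproduce the reported
    direction (higher gait variability, shorter test duration).
    ``noise_sd`` is the SD of the total-duration residual; each trial gets
    an independent residual of SD ``noise_sd / sqrt(2)``.
    """

    n_subjects: int = 19
    age_range: tuple[int, int] = (60, 95)
    height_range: tuple[float, float] = (145.0, 180.0)
    weight_range: tuple[float, float] = (40.0, 90.0)
    male_fraction: float = 15 / 19
    coupling_beta: float = -0.25
    noise_sd: float = 0.4
    duration_intercept: float = 10.0
    trial1_offset: float = 1.5
    score_rule: ScoreRule = field(default_factory=ScoreRule)
    n_frames: int = 300
    step_mean_range: tuple[float, float] = (6.0, 12.0)
    step_sd_range: tuple[float, float] = (1.0, 4.0)
    trend_range: tuple[float, float] = (-0.004, 0.004)
    lr_asymmetry_range: tuple[float, float] = (0.9, 1.1)
    dropout_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if int(self.n_subjects) < 2:
            raise ConfigError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigError(
                f"male_fraction must lie in [0, 1], got {self.male_fraction}"
            )
        for name in ("age_range", "height_range", "weight_range",
                     "step_mean_range", "step_sd_range", "trend_range",
                     "lr_asymmetry_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} must satisfy lo <= hi, got ({lo}, {hi})")


@dataclass
class CohortSimResult:
    """Simulated cohort: table, raw trials, and the features used to couple durations."""

    cohort: pd.DataFrame
    trials: dict[str, tuple[PoseSequence, PoseSequence]]
    features: pd.DataFrame


def _step_increments(
    rng: np.random.Generator,
    config: WalkSimConfig,
    phase: float,
    scale: float,
) -> np.ndarray:
    k = np.arange(config.n_frames - 1, dtype=float)
    gate = 1.0 + config.cycle_amplitude * np.sin(
        2.0 * np.pi * (k / config.cycle_period + phase)
    )
    noise = rng.normal(0.0, config.step_sd * scale, k.size)
    return np.clip((config.step_mean + config.trend * k) * scale * gate + noise, 0.0, None)


def _foot_confidences(
    rng: np.random.Generator, config: WalkSimConfig, n: int
) -> np.ndarray:
    base = rng.uniform(0.85, 1.0, n)
    drop = rng.uniform(0.0, 1.0, n) < config.dropout_rate
    low = rng.uniform(0.0, 0.1, n)
    return np.where(drop, low, base)


def simulate_walk_trial(
    config: WalkSimConfig,
    foot_phase_offset: float = 0.5,
    subject_id: str = "sim",
    trial_id: str = "t1",
) -> PoseSequence:
    """Simulate one walking trial as a 17-keypoint pose stream.

    Both feet advance along the image x-axis at fixed image height, so each
    foot's frame-to-frame Euclidean displacement equals its step increment
    exactly.  ``foot_phase_offset`` (fraction of a gait cycle) shifts the
    right foot's sinusoidal modulation to produce alternating steps when
    ``cycle_amplitude > 0``.  Non-foot keypoints are laid out as a plausible
    torso interpolated above the mid-foot point.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(config.n_frames)

    left_steps = _step_increments(rng, config, 0.0, 1.0)
    right_steps = _step_increments(
        rng, config, foot_phase_offset, config.lr_asymmetry
    )
    x_left = np.concatenate(([0.0], np.cumsum(left_steps)))
    x_right = 4.0 + np.concatenate(([0.0], np.cumsum(right_steps)))

    ground_y = 210.0
    y_left = np.full(n, ground_y - 6.0)
    y_right = np.full(n, ground_y + 6.0)
    mid_x = 0.5 * (x_left + x_right)
    hip_y, shoulder_y, head_y = ground_y - 80.0, ground_y - 140.0, ground_y - 160.0

    kp = np.zeros((n, N_KEYPOINTS, 3))
    # head: nose, eyes, ears
    kp[:, 0, 0], kp[:, 0, 1] = mid_x + 6.0, head_y
    for i, dx in ((1, 4.0), (2, 8.0)):
        kp[:, i, 0], kp[:, i, 1] = mid_x + dx, head_y - 3.0
    for i, dx in ((3, 0.0), (4, 10.0)):
        kp[:, i, 0], kp[:, i, 1] = mid_x + dx, head_y + 2.0
    # shoulders / elbows / wrists
    for i, dx in ((5, -3.0), (6, 3.0)):
        kp[:, i, 0], kp[:, i, 1] = mid_x + dx, shoulder_y
    for i, dx in ((7, -6.0), (8, 6.0)):
        kp[:, i, 0], kp[:, i, 1] = mid_x + dx, 0.5 * (shoulder_y + hip_y)
    for i, dx in ((9, -8.0), (10, 8.0)):
        kp[:, i, 0], kp[:, i, 1] = mid_x + dx, hip_y - 5.0
    # hips and knees interpolate toward each foot
    for i, dx in ((11, -3.0), (12, 3.0)):
        kp[:, i, 0], kp[:, i, 1] = mid_x + dx, hip_y
    kp[:, 13, 0], kp[:, 13, 1] = 0.5 * (x_left + mid_x), 0.5 * (hip_y + ground_y)
    kp[:, 14, 0], kp[:, 14, 1] = 0.5 * (x_right + mid_x), 0.5 * (hip_y + ground_y)
    # feet
    kp[:, LEFT_FOOT, 0], kp[:, LEFT_FOOT, 1] = x_left, y_left
    kp[:, RIGHT_FOOT, 0], kp[:, RIGHT_FOOT, 1] = x_right, y_right

    kp[:, LEFT_FOOT, 2] = _foot_confidences(rng, config, n)
    kp[:, RIGHT_FOOT, 2] = _foot_confidences(rng, config, n)
    body = [i for i in range(N_KEYPOINTS) if i not in (LEFT_FOOT, RIGHT_FOOT)]
    kp[:, body, 2] = rng.uniform(0.9, 1.0, (n, len(body)))

    return PoseSequence(subject_id=subject_id, trial_id=trial_id, keypoints=kp)


def expected_duration_correlation(
    coupling_beta: float, var_mean_sd: float, noise_sd: float
) -> float:
    """Closed-form Pearson correlation implied by the linear duration link.

    rho = beta * sigma_vm / sqrt(beta^2 * sigma_vm^2 + sigma_noise^2).
    """
    denom = math.sqrt((coupling_beta * var_mean_sd) ** 2 + noise_sd**2)
    if denom == 0.0:
        raise ConfigError("coupling_beta*var_mean_sd and noise_sd cannot both be 0")
    return coupling_beta * var_mean_sd / denom


def noise_sd_for_correlation(
    coupling_beta: float, var_mean_sd: float, rho: float
) -> float:
    """Residual SD giving a target var_mean-duration correlation ``rho``."""
    if not 0.0 < abs(rho) <= 1.0:
        raise ConfigError(f"rho must satisfy 0 < |rho| <= 1, got {rho}")
    if math.copysign(1.0, rho) != math.copysign(1.0, coupling_beta):
        raise ConfigError("rho and coupling_beta must share a sign")
    return abs(coupling_beta) * var_mean_sd * math.sqrt(1.0 / rho**2 - 1.0)


def block_exchangeable_correlation(
    within: float = 0.6, cross: float = 0.2
) -> np.ndarray:
    """4x4 correlation matrix invariant under foot-swap and trial-swap.

    Rows/columns follow the canonical feature order (var15_t1, var16_t1,
    var15_t2, var16_t2): ``within`` is the left-right correlation inside a
    trial, ``cross`` every cross-trial correlation.  Its eigenvectors are
    forced by the swap symmetries to the +/-1/2 patterns, so the PCA index
    must recover absolute loadings of exactly 0.5 on PC1 and the
    (+, +, -, -)/2 contrast on PC2.
    """
    if not (-1.0 < within < 1.0 and -1.0 < cross < 1.0):
        raise ConfigError("correlations must lie in (-1, 1)")
    R = np.full((4, 4), cross)
    R[0, 1] = R[1, 0] = R[2, 3] = R[3, 2] = within
    np.fill_diagonal(R, 1.0)
    if np.linalg.eigvalsh(R).min() <= 0:
        raise ConfigError(f"(within={within}, cross={cross}) is not positive definite")
    return R


def features_with_exact_correlation(
    corr: np.ndarray,
    n_subjects: int = 19,
    seed: int = 0,
    mean: float = 10.0,
    scale: float = 2.0,
) -> pd.DataFrame:
    """Feature table whose *sample* correlation matrix equals ``corr`` exactly.

    Random data are empirically whitened (sample covariance = identity) and
    recolored by the Cholesky factor of ``corr``, so the sample correlation
    matches to floating-point precision regardless of n.  Requires
    n_subjects > number of features.
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    if int(n_subjects) <= p:
        raise ConfigError(f"n_subjects must exceed {p}, got {n_subjects}")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(int(n_subjects), p))
    X -= X.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.min() < 1e-10:
        raise ConfigError("degenerate draw; choose another seed")
    Z = U * math.sqrt(n_subjects - 1)
    data = mean + scale * (Z @ np.linalg.cholesky(corr).T)
    frame = pd.DataFrame(data, columns=list(_features.FEATURE_COLUMNS[:p]))
    frame.insert(0, "subject_id", [f"S{i + 1:03d}" for i in range(int(n_subjects))])
    return frame


def rank2_features(
    n_subjects: int = 20, seed: int = 0, mean: float = 10.0
) -> pd.DataFrame:
    """Feature table built from exactly two independent latent factors.

    Each of the four variance columns is a fixed linear combination of two
    latent gait factors (no noise), so the centred data have rank 2 and a
    two-component PCA retains 100% of the variance.
    """
    if int(n_subjects) < 3:
        raise ConfigError(f"n_subjects must be >= 3, got {n_subjects}")
    rng = np.random.default_rng(seed)
    factors = rng.normal(size=(int(n_subjects), 2))
    weights = np.array(
        [[1.0, 0.6], [0.8, -0.5], [-0.4, 1.2], [0.7, 0.9]]
    )  # generic: no column degenerate, no pair collinear
    data = mean + factors @ weights.T
    frame = pd.DataFrame(data, columns=list(_features.FEATURE_COLUMNS))
    frame.insert(0, "subject_id", [f"S{i + 1:03d}" for i in range(int(n_subjects))])
    return frame


def simulate_cohort(config: CohortSimConfig) -> CohortSimResult:
    """Simulate a cohort table plus a pair of walking trials per subject.

    Each subject draws personal step statistics, walks both trials with
    independent noise realizations, and gets durations from the linear
    var_mean link (var_mean computed through the actual extraction pipeline,
    confidence threshold 0.3).  Reproducible under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    trials: dict[str, tuple[PoseSequence, PoseSequence]] = {}
    feature_rows: list[dict] = []
    trial_noise = config.noise_sd / math.sqrt(2.0)
    i1 = 0.5 * (config.duration_intercept + config.trial1_offset)
    i2 = 0.5 * (config.duration_intercept - config.trial1_offset)

    for i in range(int(config.n_subjects)):
        sid = f"S{i + 1:03d}"
        age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
        gender = "male" if rng.uniform() < config.male_fraction else "female"
        height = round(float(rng.uniform(*config.height_range)), 1)
        weight = round(float(rng.uniform(*config.weight_range)), 1)

        walk = WalkSimConfig(
            n_frames=config.n_frames,
            step_mean=float(rng.uniform(*config.step_mean_range)),
            step_sd=float(rng.uniform(*config.step_sd_range)),
            trend=float(rng.uniform(*config.trend_range)),
            lr_asymmetry=float(rng.uniform(*config.lr_asymmetry_range)),
            dropout_rate=config.dropout_rate,
            seed=int(rng.integers(0, 2**31)),
        )
        seq1 = simulate_walk_trial(walk, subject_id=sid, trial_id="t2_1")
        seq2 = simulate_walk_trial(
            replace(walk, seed=int(rng.integers(0, 2**31))),
            subject_id=sid,
            trial_id="t2_2",
        )
        trials[sid] = (seq1, seq2)

        feats = _features.subject_features(sid, seq1, seq2, min_confidence=0.3)
        feature_rows.append(feats)
        vm = float(feats["var_mean"])

        eps1 = float(rng.normal(0.0, trial_noise))
        eps2 = float(rng.normal(0.0, trial_noise))
        d1 = i1 + 0.5 * config.coupling_beta * vm + eps1
        d2 = i2 + 0.5 * config.coupling_beta * vm + eps2
        s1 = config.score_rule.score(d1)
        s2 = config.score_rule.score(d2)
        rows.append(
            {
                "subject_id": sid,
                "age": age,
                "gender": gender,
                "height_cm": height,
                "weight_kg": weight,
                "score2_1": s1,
                "score2_2": s2,
                "score2": max(s1, s2),
                "duration1": d1,
                "duration2": d2,
                "duration": d1 + d2,
            }
        )

    cohort = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    features = pd.DataFrame(feature_rows)
    return CohortSimResult(cohort=cohort, trials=trials, features=features)


def write_cohort(
    result: CohortSimResult, out_dir: str | Path
) -> dict[str, Path]:
    """Write a simulated cohort to disk: cohort.csv plus one JSON per trial."""
    out_dir = Path(out_dir)
    keypoint_dir = out_dir / "keypoints"
    keypoint_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    cohort_path = out_dir / "cohort.csv"
    result.cohort.to_csv(cohort_path, index=False)
    paths["cohort"] = cohort_path
    for sid, (seq1, seq2) in result.trials.items():
        for seq in (seq1, seq2):
            p = keypoint_dir / f"{sid}_{seq.trial_id}.json"
            write_keypoint_json(seq, p)
            paths[f"{sid}_{seq.trial_id}"] = p
    return paths
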