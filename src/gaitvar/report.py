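"""Baseline cohort summaries and the end-to-end pipeline orchestrator.

Baseline binning follows the study conventions: age split at 80 years (80
belongs to the 60-80 bin), height in 10 cm bins from 145 cm, weight in
10 kg bins from 40 kg with a deliberate gap at 70-85 kg (bins may have
gaps; records falling outside every bin are reported in an "unbinned"
bucket, never silently dropped).  Percentages are rounded half-up to one
decimal.

:func:`run_pipeline` chains the full analysis — simulate or load keypoint
trials and a cohort table, extract displacement-variance features, fit the
PCA index, build the mixed-type correlation matrix, summarize the cohort —
and writes every artifact with a SHA-256 manifest.  Runs are deterministic
under a fixed seed: rerunning a configuration reproduces the manifest
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from contextlib import contextmanager
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlation import (
    SmoothingConfig,
    annotate_and_export,
    classify_variables,
    compute_correlation_matrix,
)
from .errors import ConfigError, IncompleteTrialsError, PipelineStageError
from .features import features_table
from .pca import explained_frame, fit_pca_index, interpret_components, loadings_frame
from .pose_io import PoseSequence, read_keypoint_json
from .synthetic import CohortSimConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)

COHORT_VARIABLE_KINDS = {
    "gender": "binary",
    "score2_1": "ordinal",
    "score2_2": "ordinal",
    "score2": "ordinal",
}


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (the convention used for printed percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, ROUND_HALF_UP))


@dataclass(frozen=True)
class Bin:
    """One half-open (by default) numeric bin ``[lo, hi)`` with a label."""

    label: str
    lo: float
    hi: float
    lo_inclusive: bool = True
    hi_inclusive: bool = False

    def contains(self, value: float) -> bool:
        above = value >= self.lo if self.lo_inclusive else value > self.lo
        below = value <= self.hi if self.hi_inclusive else value < self.hi
        return above and below


@dataclass(frozen=True)
class BinSpec:
    """Bins for one numeric variable; bins must not overlap, gaps are fine."""

    variable: str
    bins: tuple[Bin, ...]


DEFAULT_BINS: tuple[BinSpec, ...] = (
    BinSpec("age", (
        Bin("60-80", 60, 80, hi_inclusive=True),
        Bin(">80", 80, math.inf, lo_inclusive=False),
    )),
    BinSpec("height_cm", (
        Bin("145-155", 145, 155),
        Bin("155-165", 155, 165),
        Bin("165-175", 165, 175),
        Bin(">=175", 175, math.inf),
    )),
    BinSpec("weight_kg", (
        Bin("40-50", 40, 50),
        Bin("50-60", 50, 60),
        Bin("60-70", 60, 70),
        Bin(">=85", 85, math.inf),  # the 70-85 kg range is deliberately unbinned
    )),
)


def summarize_baseline(
    cohort: pd.DataFrame,
    bin_specs: tuple[BinSpec, ...] = DEFAULT_BINS,
    categorical: tuple[str, ...] = ("gender",),
) -> pd.DataFrame:
    """Counts and percentages per baseline bin.

    Returns a tidy frame (variable, bin, count, percentage).  Numeric
    variables get an extra "unbinned" row counting records outside every
    bin; categorical variables are tabulated by level.
    """
    if cohort.empty:
        raise ConfigError("cohort table is empty")
    n = len(cohort)
    rows = []
    for spec in bin_specs:
        values = cohort[spec.variable].to_numpy(dtype=float)
        assigned = np.zeros(len(values), dtype=bool)
        for b in spec.bins:
            inside = np.array([b.contains(v) for v in values])
            if np.any(inside & assigned):
                raise ConfigError(f"overlapping bins for {spec.variable!r}")
            assigned |= inside
            count = int(inside.sum())
            rows.append(
                {
                    "variable": spec.variable,
                    "bin": b.label,
                    "count": count,
                    "percentage": round_half_up(100.0 * count / n, 1),
                }
            )
        unbinned = int((~assigned).sum())
        rows.append(
            {
                "variable": spec.variable,
                "bin": "unbinned",
                "count": unbinned,
                "percentage": round_half_up(100.0 * unbinned / n, 1),
            }
        )
    for name in categorical:
        counts = cohort[name].value_counts().sort_index()
        for level, count in counts.items():
            rows.append(
                {
                    "variable": name,
                    "bin": str(level),
                    "count": int(count),
                    "percentage": round_half_up(100.0 * count / n, 1),
                }
            )
    return pd.DataFrame(rows, columns=["variable", "bin", "count", "percentage"])


def summarize_scores_durations(cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-trial score and duration descriptives plus paired trial differences.

    Returns ``{"distribution": ..., "paired": ..., "missing": ...}`` where
    "missing" lists subjects with incomplete trial data (their rows are
    excluded from the paired differences but flagged, never dropped
    silently).
    """
    trial_cols = ["score2_1", "score2_2", "score2",
                  "duration1", "duration2", "duration"]
    missing_mask = cohort[trial_cols].isna().any(axis=1)
    missing = cohort.loc[missing_mask, ["subject_id"]].copy()
    complete = cohort.loc[~missing_mask]

    dist_rows = []
    for col in trial_cols:
        v = complete[col].to_numpy(dtype=float)
        dist_rows.append(
            {
                "variable": col,
                "n": len(v),
                "mean": float(np.mean(v)),
                "median": float(np.median(v)),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else math.nan,
                "min": float(np.min(v)),
                "max": float(np.max(v)),
            }
        )
    paired_rows = []
    for name, col1, col2 in (
        ("duration1_minus_duration2", "duration1", "duration2"),
        ("score2_1_minus_score2_2", "score2_1", "score2_2"),
    ):
        diff = complete[col1].to_numpy(float) - complete[col2].to_numpy(float)
        paired_rows.append(
            {
                "difference": name,
                "n": len(diff),
                "mean": float(np.mean(diff)),
                "median": float(np.median(diff)),
                "sd": float(np.std(diff, ddof=1)) if len(diff) > 1 else math.nan,
            }
        )
    return {
        "distribution": pd.DataFrame(dist_rows),
        "paired": pd.DataFrame(paired_rows),
        "missing": missing,
    }


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Provide either ``simulate`` (a :class:`CohortSimConfig`) or both
    ``keypoint_dir`` (one ``<subject>_<trial>.json`` per trial, two trials
    per subject) and ``cohort_csv``.
    """

    out_dir: Path
    simulate: CohortSimConfig | None = None
    keypoint_dir: Path | None = None
    cohort_csv: Path | None = None
    min_confidence: float = 0.3
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    fdr_method: str = "fdr_bh"
    make_plots: bool = True
    write_trials: bool = False

    def validate(self) -> None:
        if self.simulate is None and (self.keypoint_dir is None or self.cohort_csv is None):
            raise ConfigError(
                "provide simulate=CohortSimConfig or keypoint_dir + cohort_csv"
            )


@dataclass
class PipelineResult:
    """Everything a pipeline run produced, plus the manifest."""

    cohort: pd.DataFrame
    features: pd.DataFrame
    pca_loadings: pd.DataFrame
    pca_explained: pd.DataFrame
    component_labels: tuple[str, str]
    merged: pd.DataFrame
    correlations: pd.DataFrame
    baseline: pd.DataFrame
    score_duration: dict[str, pd.DataFrame]
    manifest: dict
    manifest_path: Path


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc


def _load_trials_from_dir(
    keypoint_dir: Path,
) -> dict[str, tuple[PoseSequence, PoseSequence]]:
    files = sorted(Path(keypoint_dir).glob("*.json"))
    if not files:
        raise ConfigError(f"no keypoint JSON files in {keypoint_dir}")
    by_subject: dict[str, list[PoseSequence]] = {}
    for path in files:
        seq = read_keypoint_json(path)
        by_subject.setdefault(seq.subject_id, []).append(seq)
    trials: dict[str, tuple[PoseSequence, PoseSequence]] = {}
    for sid, seqs in by_subject.items():
        if len(seqs) != 2:
            raise IncompleteTrialsError(
                f"subject {sid!r}: found {len(seqs)} trial file(s), expected 2"
            )
        seqs = sorted(seqs, key=lambda s: s.trial_id)
        trials[sid] = (seqs[0], seqs[1])
    return trials


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _config_echo(config: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    raw = {f.name: getattr(config, f.name) for f in dataclasses.fields(config)}
    return {k: convert(v) for k, v in raw.items()}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write all artifacts under ``config.out_dir``.

    Stages: load/simulate -> features -> pca -> correlate -> report ->
    write.  Any stage failure propagates as :class:`PipelineStageError`
    carrying the stage name (and subject context where applicable).
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("gaitvar")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    try:
        with _stage("load"):
            if config.simulate is not None:
                sim = simulate_cohort(config.simulate)
                cohort, trials = sim.cohort, sim.trials
                logger.info("simulated cohort of %d subjects", len(cohort))
            else:
                trials = _load_trials_from_dir(Path(config.keypoint_dir))
                cohort = pd.read_csv(config.cohort_csv)
                logger.info(
                    "loaded %d subjects' trials from %s",
                    len(trials), config.keypoint_dir,
                )

        with _stage("features"):
            features = features_table(trials, min_confidence=config.min_confidence)

        with _stage("pca"):
            index = fit_pca_index(features)
            labels = interpret_components(index)
            pca_loadings = loadings_frame(index)
            pca_explained = explained_frame(index)
            logger.info(
                "PCA explained ratios %.3f / %.3f; components: %s / %s",
                *index.explained_ratio, *labels,
            )

        with _stage("correlate"):
            merged = cohort.merge(
                features[["subject_id", "var_mean", "var_mean_2_1", "var_mean_2_2"]],
                on="subject_id",
                validate="one_to_one",
            ).merge(index.scores, on="subject_id", validate="one_to_one")
            specs = classify_variables(merged, overrides=COHORT_VARIABLE_KINDS)
            matrix = compute_correlation_matrix(
                specs, smoothing=config.smoothing, fdr_method=config.fdr_method
            )
            correlations = matrix.long_frame()

        with _stage("report"):
            baseline = summarize_baseline(cohort)
            score_duration = summarize_scores_durations(cohort)

        with _stage("write"):
            artifacts: dict[str, Path] = {}

            def emit(name: str, frame: pd.DataFrame) -> None:
                path = out_dir / name
                frame.to_csv(path, index=False)
                artifacts[name] = path

            emit("cohort.csv", cohort)
            emit("features.csv", features)
            emit("pca_loadings.csv", pca_loadings)
            emit("pca_explained.csv", pca_explained)
            emit("subject_scores.csv", index.scores)
            emit("merged_table.csv", merged)
            emit("correlations.csv", correlations)
            emit("baseline.csv", baseline)
            emit("score_duration_distribution.csv", score_duration["distribution"])
            emit("score_duration_paired.csv", score_duration["paired"])
            if config.make_plots:
                heatmap = annotate_and_export(
                    matrix,
                    out_dir / "correlation_matrix.csv",
                    heatmap_path=out_dir / "correlation_heatmap.png",
                    title="Gait-variability index vs SPPB Test 2",
                )
                artifacts["correlation_matrix.csv"] = heatmap["csv"]
                artifacts["correlation_heatmap.png"] = heatmap["heatmap"]
            if config.write_trials and config.simulate is not None:
                written = write_cohort(sim, out_dir / "data")
                for key, path in written.items():
                    artifacts[f"data/{path.name}"] = path

            manifest = {
                "package": "gaitvar",
                "version": __version__,
                "config": _config_echo(config),
                "n_subjects": int(len(cohort)),
                "component_labels": list(labels),
                "artifacts": [
                    {
                        "name": name,
                        "bytes": Path(path).stat().st_size,
                        "sha256": _sha256(Path(path)),
                    }
                    for name, path in sorted(artifacts.items())
                ],
            }
            manifest_path = out_dir / "manifest.json"
            with open(manifest_path, "w", encoding="utf-8") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True)
                fh.write("\n")
    finally:
        root.removeHandler(handler)
        handler.close()

    return PipelineResult(
        cohort=cohort,
        features=features,
        pca_loadings=pca_loadings,
        pca_explained=pca_explained,
        component_labels=labels,
        merged=merged,
        correlations=correlations,
        baseline=baseline,
        score_duration=score_duration,
        manifest=manifest,
        manifest_path=manifest_path,
    )
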