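"""Per-trial gait-displacement features and the composite variability index.

For one foot in one trial with surviving coordinates (x_k, y_k), the
frame-to-frame movement distance is the Euclidean displacement

    d_k = sqrt((x_{k+1} - x_k)^2 + (y_{k+1} - y_k)^2),  k = 1 .. N-1,

and its fluctuation magnitude is the unbiased sample variance of the d_k
(denominator = count of displacements minus one) about the same trial's mean
displacement.  The composite index averages the
four per-foot, per-trial variances:

    var_mean = (var15_t1 + var16_t1 + var15_t2 + var16_t2) / 4,

with per-trial means var_mean_2_j = (var15_tj + var16_tj) / 2.  "t1"/"t2"
are the two consecutive walks of SPPB Test 2 (trials 2.1 and 2.2); 15/16 are
the left/right foot keypoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import IncompleteTrialsError, InsufficientFramesError
from .pose_io import FootTrack, PoseSequence, extract_foot_tracks

#: canonical feature-table columns, in loading order for the PCA stage
FEATURE_COLUMNS = ("var15_t1", "var16_t1", "var15_t2", "var16_t2")
COMPOSITE_COLUMNS = ("var_mean_2_1", "var_mean_2_2", "var_mean")
TRIAL_IDS = ("t1", "t2")


@dataclass
class DisplacementSeries:
    """The N-1 per-frame displacements of one foot in one trial (pixels)."""

    foot_index: int
    trial_id: str
    values: np.ndarray
    #: True where the displacement spans a confidence-filtering gap
    spans_gap: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class TrialVariance:
    """Unbiased variance (pixels^2) of one displacement series."""

    foot_index: int
    trial_id: str
    variance: float
    mean_displacement: float
    n: int


def frame_displacements(
    track: FootTrack, trial_id: str = "", skip_gap_spanning: bool = False
) -> DisplacementSeries:
    """Euclidean displacements between consecutive surviving frames.

    When frames were dropped by confidence filtering, the two flanking
    displacements merge into a single displacement across the gap; with
    ``skip_gap_spanning`` those merged values are excluded instead.
    """
    if len(track) < 2:
        raise InsufficientFramesError(
            f"foot {track.foot_index}: need at least 2 coordinates, have {len(track)}"
        )
    deltas = np.diff(track.coords, axis=0)
    values = np.hypot(deltas[:, 0], deltas[:, 1])
    spans_gap = np.diff(track.frame_indices) > 1
    if skip_gap_spanning:
        values = values[~spans_gap]
        spans_gap = np.zeros(values.shape, dtype=bool)
    return DisplacementSeries(track.foot_index, trial_id, values, spans_gap)


def displacement_variance(series: DisplacementSeries) -> TrialVariance:
    """Unbiased sample variance of a displacement series (denominator n-1)."""
    values = np.asarray(series.values, dtype=float)
    n = values.size
    if n < 2:
        raise InsufficientFramesError(
            f"foot {series.foot_index}, trial {series.trial_id!r}: variance "
            f"undefined for {n} displacement(s); need at least 2"
        )
    mean = float(values.mean())
    variance = float(np.sum((values - mean) ** 2) / (n - 1))
    return TrialVariance(series.foot_index, series.trial_id, variance, mean, n)


def composite_var_mean(variances: Mapping[tuple[int, str], float]) -> dict[str, float]:
    """Combine the four per-foot/per-trial variances into the composite index.

    ``variances`` maps ``(foot_index, trial_id)`` -> variance with
    foot_index in {15, 16} and trial_id in {"t1", "t2"}.  Raises
    :class:`IncompleteTrialsError` listing anything absent; no term is ever
    silently dropped.
    """
    required = [(15, "t1"), (16, "t1"), (15, "t2"), (16, "t2")]
    missing = [key for key in required if key not in variances]
    if missing:
        human = ", ".join(f"foot {f} trial {t}" for f, t in missing)
        raise IncompleteTrialsError(f"incomplete trials: missing {human}")
    v15_t1, v16_t1 = variances[(15, "t1")], variances[(16, "t1")]
    v15_t2, v16_t2 = variances[(15, "t2")], variances[(16, "t2")]
    return {
        "var15_t1": v15_t1,
        "var16_t1": v16_t1,
        "var15_t2": v15_t2,
        "var16_t2": v16_t2,
        "var_mean_2_1": (v15_t1 + v16_t1) / 2.0,
        "var_mean_2_2": (v15_t2 + v16_t2) / 2.0,
        "var_mean": (v15_t1 + v16_t1 + v15_t2 + v16_t2) / 4.0,
    }


def subject_features(
    subject_id: str,
    trial1: PoseSequence,
    trial2: PoseSequence,
    min_confidence: float = 0.3,
    skip_gap_spanning: bool = False,
) -> dict[str, float | str]:
    """Full feature vector for one subject's pair of walking trials."""
    variances: dict[tuple[int, str], float] = {}
    for trial_id, seq in zip(TRIAL_IDS, (trial1, trial2)):
        if seq is None:
            raise IncompleteTrialsError(
                f"subject {subject_id!r}: missing trial {trial_id!r}"
            )
        left, right = extract_foot_tracks(seq, min_confidence)
        for track in (left, right):
            series = frame_displacements(track, trial_id, skip_gap_spanning)
            variances[(track.foot_index, trial_id)] = displacement_variance(
                series
            ).variance
    row: dict[str, float | str] = {"subject_id": subject_id}
    row.update(composite_var_mean(variances))
    return row


def features_table(
    trials: Mapping[str, tuple[PoseSequence | None, PoseSequence | None]],
    min_confidence: float = 0.3,
    skip_gap_spanning: bool = False,
) -> pd.DataFrame:
    """Feature table over a cohort: one row per subject.

    Any failure is re-raised with the subject named so pipeline errors carry
    their context.
    """
    rows = []
    for subject_id, pair in trials.items():
        if len(pair) != 2:
            raise IncompleteTrialsError(
                f"subject {subject_id!r}: expected 2 trials, found {len(pair)}"
            )
        try:
            rows.append(
                subject_features(
                    subject_id, pair[0], pair[1], min_confidence, skip_gap_spanning
                )
            )
        except IncompleteTrialsError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise type(exc)(f"subject {subject_id!r}: {exc}") from exc
    columns = ["subject_id", *FEATURE_COLUMNS, *COMPOSITE_COLUMNS]
    return pd.DataFrame(rows, columns=columns)
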