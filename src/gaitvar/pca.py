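"""Correlation-matrix PCA over the four per-foot/per-trial gait variances.

The four features (var15_t1, var16_t1, var15_t2, var16_t2) are z-scored and
the sample correlation matrix eigendecomposed; the top two components form
the gait index.  With four standardized variables the explained-variance
ratio of a component is its eigenvalue divided by 4 (the trace of the
correlation matrix), and for rank-2 feature data the two ratios sum to 1.

Sign conventions are deterministic so outputs are reproducible across
linear-algebra backends:

* PC1 is oriented so its loading sum is positive.  When all four loadings
  share one sign, PC1 reads as a "muscle-control reserve" axis: overall
  gait-adjustment capacity moving all variances together.
* PC2 is oriented so the trial-1 loadings are positive.  When trial-1 and
  trial-2 loadings oppose, PC2 reads as a "learning-fatigue response" axis:
  positive scores mean more variability in the first walk (initial caution),
  negative scores more in the second (fatigue).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InsufficientDataError
from .features import FEATURE_COLUMNS

_SIGN_TOL = 1e-12


@dataclass
class PCAIndex:
    """Fitted two-component gait index.

    ``loadings`` is 4x2 (rows in ``columns`` order), columns orthonormal;
    ``explained_ratio`` holds the two explained-variance fractions;
    ``scores`` has one (PC1, PC2) row per subject.
    """

    loadings: np.ndarray
    explained_ratio: np.ndarray
    scores: pd.DataFrame
    eigenvalues: np.ndarray
    columns: tuple[str, ...]
    standardized: bool


def _orient_sign(vec: np.ndarray, preferred: np.ndarray) -> np.ndarray:
    """Flip ``vec`` so that ``preferred @ vec`` is positive.

    Fallbacks: the full loading sum, then the first nonzero entry, so the
    orientation is total (no vector is left ambiguous).
    """
    for weights in (preferred, np.ones_like(vec)):
        s = float(weights @ vec)
        if abs(s) > _SIGN_TOL:
            return vec if s > 0 else -vec
    for v in vec:
        if abs(v) > _SIGN_TOL:
            return vec if v > 0 else -vec
    return vec


def fit_pca_index(
    features: pd.DataFrame,
    columns: Sequence[str] = FEATURE_COLUMNS,
    standardize: bool = True,
) -> PCAIndex:
    """Fit the two-component PCA gait index.

    ``features`` must contain the four variance columns with no missing
    values and at least 3 subjects.  ``standardize=False`` switches to
    covariance-matrix PCA (centred but unscaled); the default follows the
    correlation-matrix convention under which symmetric feature structures
    yield the +/-0.5 loading patterns the index is interpreted by.
    """
    columns = tuple(columns)
    X = features[list(columns)].to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise InsufficientDataError(f"PCA needs at least 3 subjects, got {n}")
    if np.isnan(X).any():
        raise InsufficientDataError("PCA input contains missing values")

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0.0)
    if standardize and zero.size:
        names = ", ".join(columns[j] for j in zero)
        raise DegenerateDataError(f"zero-variance column(s): {names}")
    Z = (X - mean) / sd if standardize else X - mean

    C = (Z.T @ Z) / (n - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(-evals, kind="stable")
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    half = p // 2
    trial1_weights = np.zeros(p)
    trial1_weights[:half] = 1.0
    l1 = _orient_sign(evecs[:, 0].copy(), np.ones(p))
    l2 = _orient_sign(evecs[:, 1].copy(), trial1_weights)
    loadings = np.column_stack([l1, l2])

    trace = float(np.trace(C))
    explained = evals[:2] / trace
    scores = pd.DataFrame(Z @ loadings, columns=["PC1", "PC2"])
    if "subject_id" in features.columns:
        scores.insert(0, "subject_id", features["subject_id"].to_numpy())

    return PCAIndex(
        loadings=loadings,
        explained_ratio=explained,
        scores=scores,
        eigenvalues=evals,
        columns=columns,
        standardized=standardize,
    )


PC1_LABEL = "muscle-control reserve"
PC2_LABEL = "learning-fatigue response"
UNSTRUCTURED = "unstructured"


def interpret_components(index: PCAIndex, tol: float = 1e-10) -> tuple[str, str]:
    """Label the two components by their loading sign structure.

    PC1 is a muscle-control-reserve axis iff all four loadings share one
    sign; PC2 is a learning-fatigue-response axis iff trial-1 and trial-2
    loadings have opposite signs.  Anything else is "unstructured" — no
    interpretation is forced.
    """
    l1, l2 = index.loadings[:, 0], index.loadings[:, 1]
    half = len(l1) // 2

    if np.all(l1 > tol) or np.all(l1 < -tol):
        label1 = PC1_LABEL
    else:
        label1 = UNSTRUCTURED

    first, second = l2[:half], l2[half:]
    if (np.all(first > tol) and np.all(second < -tol)) or (
        np.all(first < -tol) and np.all(second > tol)
    ):
        label2 = PC2_LABEL
    else:
        label2 = UNSTRUCTURED
    return label1, label2


def loadings_frame(index: PCAIndex) -> pd.DataFrame:
    """Loadings as a tidy table (one row per feature)."""
    return pd.DataFrame(
        index.loadings, columns=["PC1", "PC2"], index=list(index.columns)
    ).rename_axis("feature").reset_index()


def explained_frame(index: PCAIndex) -> pd.DataFrame:
    """Explained-variance ratios as a tidy table."""
    return pd.DataFrame(
        {
            "component": ["PC1", "PC2"],
            "explained_ratio": index.explained_ratio,
            "eigenvalue": index.eigenvalues[:2],
        }
    )
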