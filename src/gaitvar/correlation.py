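"""Mixed-variable-type correlation engine with FDR control.

Variables are classified as binary (gender), ordinal (SPPB test scores) or
continuous (demographics, durations, gait features, PC scores), then each
pair is correlated with the coefficient appropriate to its kind pair:

==========  ==========  ====================
kind A      kind B      method
==========  ==========  ====================
binary      binary      undefined (blank cell)
binary      other       point-biserial
ordinal     ordinal     Kendall tau-b
continuous  continuous  Pearson
ordinal     continuous  Spearman
==========  ==========  ====================

Before correlating, ordinal variables are converted to midranks and
z-scored; continuous variables may optionally be LOWESS-smoothed against
subject order (off by default — smoothing alters classical coefficient
properties, so it is an explicit choice).  Two-sided p-values come from the
classical asymptotic forms (an exact permutation option exists for tiny n)
and are Benjamini-Hochberg adjusted across all reported off-diagonal pairs.
Stars annotate the adjusted p-values: * < 0.05, ** < 0.01, *** < 0.001.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DegenerateDataError, InsufficientDataError

logger = logging.getLogger(__name__)

KINDS = ("binary", "ordinal", "continuous")

#: kind-pair -> coefficient dispatch (order-insensitive)
DISPATCH_TABLE: dict[frozenset[str], str] = {
    frozenset(["binary"]): "undefined_default",
    frozenset(["binary", "ordinal"]): "point_biserial",
    frozenset(["binary", "continuous"]): "point_biserial",
    frozenset(["ordinal"]): "kendall_tau",
    frozenset(["continuous"]): "pearson",
    frozenset(["ordinal", "continuous"]): "spearman",
}

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class SmoothingConfig:
    """LOWESS preprocessing of continuous variables (against subject order)."""

    enabled: bool = False
    frac: float = 0.5

    def validate(self) -> None:
        if not 0.0 < self.frac <= 1.0:
            raise ConfigError(f"frac must lie in (0, 1], got {self.frac}")


@dataclass
class VariableSpec:
    """A named per-subject variable with its declared kind."""

    name: str
    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        self.values = np.asarray(self.values)
        if self.kind == "binary" and len(pd.unique(self.values[~pd.isna(self.values)])) > 2:
            raise ConfigError(f"binary variable {self.name!r} has > 2 levels")


@dataclass
class CorrelationResult:
    """One pairwise coefficient with raw/adjusted p-values and stars."""

    pair: tuple[str, str]
    method: str
    coefficient: float = math.nan
    p_raw: float = math.nan
    p_adjusted: float = math.nan
    stars: str = ""
    note: str = ""

    @property
    def defined(self) -> bool:
        return math.isfinite(self.coefficient)


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of pairwise results over an ordered variable list."""

    variables: list[str]
    results: dict[tuple[str, str], CorrelationResult]

    def get(self, a: str, b: str) -> CorrelationResult:
        return self.results[(a, b) if (a, b) in self.results else (b, a)]

    def coefficient_frame(self) -> pd.DataFrame:
        v = self.variables
        mat = pd.DataFrame(np.nan, index=v, columns=v)
        for (a, b), r in self.results.items():
            mat.loc[a, b] = r.coefficient
            mat.loc[b, a] = r.coefficient
        return mat

    def annotation_frame(self) -> pd.DataFrame:
        v = self.variables
        mat = pd.DataFrame("", index=v, columns=v, dtype=object)
        for (a, b), r in self.results.items():
            text = format_coefficient(r.coefficient, r.stars)
            mat.loc[a, b] = text
            mat.loc[b, a] = text
        return mat

    def long_frame(self, include_diagonal: bool = False) -> pd.DataFrame:
        rows = []
        for (a, b), r in self.results.items():
            if a == b and not include_diagonal:
                continue
            rows.append(
                {
                    "var_a": a,
                    "var_b": b,
                    "method": r.method,
                    "coefficient": r.coefficient,
                    "p_raw": r.p_raw,
                    "p_adjusted": r.p_adjusted,
                    "stars": r.stars,
                    "note": r.note,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["var_a", "var_b", "method", "coefficient", "p_raw",
                     "p_adjusted", "stars", "note"],
        )


def classify_variables(
    table: pd.DataFrame,
    overrides: Mapping[str, str] | None = None,
    exclude: Sequence[str] = ("subject_id",),
    max_ordinal_levels: int = 6,
) -> list[VariableSpec]:
    """Classify table columns as binary / ordinal / continuous.

    Auto-detection: two distinct values -> binary; integer-valued numerics
    with at most ``max_ordinal_levels`` distinct values -> ordinal; other
    numerics -> continuous.  ``overrides`` (name -> kind) always win.
    Constant columns are excluded with a warning, never correlated.
    """
    if table.empty:
        raise InsufficientDataError("cannot classify an empty table")
    overrides = dict(overrides or {})
    specs: list[VariableSpec] = []
    for name in table.columns:
        if name in exclude:
            continue
        series = table[name]
        values = series.to_numpy()
        distinct = series.dropna().unique()
        if len(distinct) <= 1:
            logger.warning("column %r is constant; excluded from correlation", name)
            continue
        if name in overrides:
            kind = overrides[name]
        elif len(distinct) == 2:
            kind = "binary"
        elif pd.api.types.is_numeric_dtype(series):
            numeric = series.dropna().to_numpy(dtype=float)
            integral = np.allclose(numeric, np.round(numeric))
            kind = "ordinal" if integral and len(distinct) <= max_ordinal_levels else "continuous"
        else:
            logger.warning(
                "column %r is non-numeric with >2 levels; excluded", name
            )
            continue
        specs.append(VariableSpec(name=name, kind=kind, values=values))
    return specs


def preprocess(
    spec: VariableSpec, smoothing: SmoothingConfig | None = None
) -> np.ndarray:
    """Transform a variable for correlation.

    binary -> 0/1 coding (levels in sorted order); ordinal -> midranks then
    z-scores; continuous -> optional LOWESS smoothing against subject order,
    identity when smoothing is disabled.
    """
    smoothing = smoothing or SmoothingConfig()
    smoothing.validate()
    if spec.kind == "binary":
        levels = sorted(pd.unique(spec.values[~pd.isna(spec.values)]))
        return (spec.values == levels[-1]).astype(float)
    if spec.kind == "ordinal":
        ranks = stats.rankdata(spec.values.astype(float))
        sd = ranks.std(ddof=1)
        if sd == 0.0:
            raise DegenerateDataError(
                f"ordinal variable {spec.name!r} is entirely tied"
            )
        return (ranks - ranks.mean()) / sd
    values = spec.values.astype(float)
    if smoothing.enabled:
        order = np.arange(len(values), dtype=float)
        return lowess(values, order, frac=smoothing.frac, return_sorted=False)
    return values


def dispatch_method(kind_a: str, kind_b: str) -> str:
    """The coefficient mandated for a pair of variable kinds."""
    return DISPATCH_TABLE[frozenset([kind_a, kind_b])]


def _p_from_permutation(
    x: np.ndarray, y: np.ndarray, statistic, n_resamples: int, seed: int
) -> float:
    method = stats.PermutationMethod(
        n_resamples=n_resamples, random_state=np.random.default_rng(seed)
    )
    return float(statistic(x, y, method=method).pvalue)


def pairwise_correlation(
    a: VariableSpec,
    b: VariableSpec,
    smoothing: SmoothingConfig | None = None,
    p_method: str = "asymptotic",
    permutation_seed: int = 0,
) -> CorrelationResult:
    """Correlate one pair with the kind-appropriate coefficient.

    Rows with a missing value in either variable are dropped pairwise; fewer
    than 3 complete pairs is an error.  ``p_method="permutation"`` switches
    to permutation p-values (exact for very small n) for the rank-free
    coefficients.
    """
    method = dispatch_method(a.kind, b.kind)
    pair = (a.name, b.name)
    if method == "undefined_default":
        return CorrelationResult(
            pair=pair, method=method, note="binary-binary pair: no coefficient defined"
        )

    xa, xb = preprocess(a, smoothing), preprocess(b, smoothing)
    mask = ~(pd.isna(xa) | pd.isna(xb))
    xa, xb = np.asarray(xa, float)[mask], np.asarray(xb, float)[mask]
    if xa.size < 3:
        raise InsufficientDataError(
            f"pair {pair}: only {xa.size} complete observations; need >= 3"
        )
    if np.std(xa) == 0.0 or np.std(xb) == 0.0:
        return CorrelationResult(
            pair=pair, method=method, note="zero variance after preprocessing"
        )

    if method in ("pearson", "point_biserial"):
        res = stats.pearsonr(xa, xb)
        coef, p = float(res.statistic), float(res.pvalue)
        if p_method == "permutation":
            p = _p_from_permutation(xa, xb, stats.pearsonr, 100_000, permutation_seed)
    elif method == "spearman":
        res = stats.spearmanr(xa, xb)
        coef, p = float(res.statistic), float(res.pvalue)
    elif method == "kendall_tau":
        res = stats.kendalltau(xa, xb, variant="b")
        coef, p = float(res.statistic), float(res.pvalue)
    else:  # pragma: no cover - dispatch table is closed
        raise ConfigError(f"unknown method {method!r}")
    return CorrelationResult(pair=pair, method=method, coefficient=coef, p_raw=p)


def fdr_adjust(
    results: Sequence[CorrelationResult], method: str = "fdr_bh"
) -> list[CorrelationResult]:
    """Benjamini-Hochberg (or sibling) adjustment over all defined p-values.

    Returns new results with ``p_adjusted`` and stars filled; undefined
    cells pass through untouched.  Adjusted values are monotone in the raw
    p-values, never below them, and capped at 1.
    """
    results = list(results)
    idx = [i for i, r in enumerate(results) if math.isfinite(r.p_raw)]
    adjusted = list(results)
    if idx:
        raw = [results[i].p_raw for i in idx]
        _, p_adj, _, _ = multipletests(raw, alpha=0.05, method=method)
        for i, p in zip(idx, p_adj):
            r = results[i]
            adjusted[i] = replace(r, p_adjusted=float(p), stars=star_annotation(p))
    return adjusted


def star_annotation(p_adjusted: float) -> str:
    """Significance stars for an adjusted p-value."""
    if p_adjusted is None or not math.isfinite(p_adjusted):
        return ""
    for threshold, stars in STAR_THRESHOLDS:
        if p_adjusted < threshold:
            return stars
    return ""


def format_coefficient(coefficient: float, stars: str = "") -> str:
    """Render a coefficient to 2 decimals (half-up) with its stars.

    Undefined coefficients render as an empty string (blank heatmap cell).
    """
    if coefficient is None or not math.isfinite(coefficient):
        return ""
    text = str(Decimal(repr(coefficient)).quantize(Decimal("0.01"), ROUND_HALF_UP))
    if text == "-0.00":
        text = "0.00"
    return f"{text}{stars}"


def compute_correlation_matrix(
    specs: Sequence[VariableSpec],
    smoothing: SmoothingConfig | None = None,
    fdr_method: str = "fdr_bh",
    p_method: str = "asymptotic",
) -> CorrelationMatrix:
    """Full pairwise matrix: dispatch, correlate, FDR-adjust, assemble.

    The FDR family is every off-diagonal pair in the matrix.  Diagonal
    cells are fixed at 1 for ordinal/continuous variables and blank for
    binary ones (a binary self-pair is a binary-binary combination).
    """
    specs = list(specs)
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate variable names")
    off_diag: list[CorrelationResult] = []
    for i, a in enumerate(specs):
        for b in specs[i + 1 :]:
            off_diag.append(
                pairwise_correlation(a, b, smoothing=smoothing, p_method=p_method)
            )
    off_diag = fdr_adjust(off_diag, method=fdr_method)

    results: dict[tuple[str, str], CorrelationResult] = {}
    for spec in specs:
        if spec.kind == "binary":
            results[(spec.name, spec.name)] = CorrelationResult(
                pair=(spec.name, spec.name),
                method="undefined_default",
                note="binary self-pair",
            )
        else:
            results[(spec.name, spec.name)] = CorrelationResult(
                pair=(spec.name, spec.name), method="self", coefficient=1.0
            )
    for r in off_diag:
        results[r.pair] = r
    return CorrelationMatrix(variables=names, results=results)


def annotate_and_export(
    matrix: CorrelationMatrix,
    csv_path: str | Path,
    heatmap_path: str | Path | None = None,
    title: str | None = None,
) -> dict[str, Path]:
    """Write the long-format CSV and (optionally) an annotated heatmap."""
    csv_path = Path(csv_path)
    matrix.long_frame().to_csv(csv_path, index=False)
    written = {"csv": csv_path}
    if heatmap_path is not None:
        written["heatmap"] = plot_heatmap(matrix, heatmap_path, title=title)
    return written


def plot_heatmap(
    matrix: CorrelationMatrix, path: str | Path, title: str | None = None
) -> Path:
    """Annotated coefficient heatmap ("-0.96***" style cells)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    coef = matrix.coefficient_frame()
    annot = matrix.annotation_frame()
    n = len(matrix.variables)
    fig, ax = plt.subplots(figsize=(1.0 + 0.85 * n, 0.8 + 0.7 * n))
    sns.heatmap(
        coef,
        annot=annot,
        fmt="",
        cmap="vlag",
        vmin=-1.0,
        vmax=1.0,
        center=0.0,
        square=True,
        linewidths=0.5,
        cbar_kws={"shrink": 0.8},
        annot_kws={"fontsize": 7},
        ax=ax,
    )
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
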