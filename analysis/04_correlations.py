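#!/usr/bin/env python
"""Mixed-type correlation analysis of the gait index against test outcomes.

Merges cohort, features and PC scores; classifies variables (gender binary,
test scores ordinal, the rest continuous); dispatches the kind-appropriate
coefficient per pair; Benjamini-Hochberg-adjusts the p-values; and writes
the long-format results plus an annotated heatmap.  Prints the headline
cells: var_mean and the PCs against durations and scores.
"""

from pathlib import Path

import pandas as pd

from gaitvar import (
    classify_variables,
    compute_correlation_matrix,
    annotate_and_export,
    fit_pca_index,
    format_coefficient,
)
from gaitvar.report import COHORT_VARIABLE_KINDS

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    tables = ROOT / "results" / "tables"
    try:
        cohort = pd.read_csv(tables / "cohort.csv")
        features = pd.read_csv(tables / "features.csv")
    except FileNotFoundError:
        raise SystemExit("run analysis/01 and analysis/02 first")

    index = fit_pca_index(features)
    merged = cohort.merge(
        features[["subject_id", "var_mean", "var_mean_2_1", "var_mean_2_2"]],
        on="subject_id",
    ).merge(index.scores, on="subject_id")

    specs = classify_variables(merged, overrides=COHORT_VARIABLE_KINDS)
    matrix = compute_correlation_matrix(specs)

    figures = ROOT / "results" / "figures"
    figures.mkdir(parents=True, exist_ok=True)
    annotate_and_export(matrix, tables / "correlations.csv",
                        heatmap_path=figures / "correlation_heatmap.png",
                        title="Gait-variability index vs SPPB Test 2")

    def cell(a: str, b: str) -> str:
        r = matrix.get(a, b)
        return format_coefficient(r.coefficient, r.stars) or "(undefined)"

    print("headline correlations (coefficient + FDR-adjusted stars):")
    for b in ("duration", "duration1", "duration2"):
        print(f"  var_mean vs {b:<10} {cell('var_mean', b)}")
    for a in ("PC1", "PC2"):
        print(f"  {a:<8} vs duration   {cell(a, 'duration')}")
    for b in ("score2_1", "score2_2"):
        print(f"  var_mean vs {b:<10} {cell('var_mean', b)}")
    print(f"full matrix -> {tables / 'correlations.csv'}; "
          f"heatmap -> {figures / 'correlation_heatmap.png'}")


if __name__ == "__main__":
    main()
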