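#!/usr/bin/env python
"""Fit the two-component PCA gait index on the four variance features.

Standardizes the four per-foot/per-trial variances, eigendecomposes their
sample correlation matrix, and writes loadings, explained-variance ratios
and per-subject (PC1, PC2) scores under results/tables/.  Prints the
component interpretation implied by the loading signs.
"""

from pathlib import Path

import pandas as pd

from gaitvar import (
    explained_frame,
    fit_pca_index,
    interpret_components,
    loadings_frame,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    tables = ROOT / "results" / "tables"
    features_csv = tables / "features.csv"
    if not features_csv.exists():
        raise SystemExit("run analysis/02_extract_features.py first")

    features = pd.read_csv(features_csv)
    index = fit_pca_index(features)
    labels = interpret_components(index)

    loadings_frame(index).to_csv(tables / "pca_loadings.csv", index=False)
    explained_frame(index).to_csv(tables / "pca_explained.csv", index=False)
    index.scores.to_csv(tables / "pca_scores.csv", index=False)

    print("PCA over (var15_t1, var16_t1, var15_t2, var16_t2), "
          "correlation-matrix convention")
    print(loadings_frame(index).to_string(index=False,
                                          float_format=lambda v: f"{v:+.3f}"))
    print(f"explained ratios: PC1 {index.explained_ratio[0]:.3f}, "
          f"PC2 {index.explained_ratio[1]:.3f} "
          f"(cumulative {100 * index.explained_ratio.sum():.1f}%)")
    print(f"PC1 reads as: {labels[0]}; PC2 reads as: {labels[1]}")


if __name__ == "__main__":
    main()
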