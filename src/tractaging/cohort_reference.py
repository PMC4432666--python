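"""Published summary tables of the longitudinal aging cohort this pipeline
emulates (N = 76, three study waves of 1.5 T DWI).

These are inputs, not computed results: the detection-count matrix between
the five subcortical seed regions (per hemisphere) and the eleven frontal
white-matter target regions, and the printed per-connection annual FA change
rates of the two-wave (full cohort) and three-wave (N = 24 subsample)
analyses.  The package's own rules (20-fiber bundle threshold, 90%-of-cohort
detection criterion, subject-first-then-average percentage change) are
applied to these numbers to reproduce the study's summary figures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .toi import DetectionMatrix, cohort_detection_filter

COHORT_SIZE = 76
SUBSAMPLE_SIZE = 24

SEED_REGIONS = ["thalamus", "caudate", "putamen", "pallidum", "accumbens"]
TARGET_REGIONS = [
    "SF", "CAC", "RAC", "MOF", "LOF", "FP", "PO", "PT", "POC", "RMF", "CMF",
]
HEMISPHERES = ["LH", "RH"]

# Number of subjects (of 76) in whom each seed-target connection reached the
# 20-fiber bundle threshold; NA = never detected.  Rows: seed per hemisphere.
_COUNTS = {
    ("LH", "thalamus"):  [69, 38, 11, 44, 43, 4, 43, 6, 4, 71, 38],
    ("RH", "thalamus"):  [66, 45, 7, 18, 44, 4, 5, 24, 7, 73, 48],
    ("LH", "caudate"):   [71, 34, 54, 72, 72, 29, 11, 38, 3, 72, 14],
    ("RH", "caudate"):   [53, 25, 16, 71, 72, 38, 2, 8, np.nan, 74, 5],
    ("LH", "putamen"):   [69, 25, 18, 74, 76, 17, 62, 73, 48, 74, 61],
    ("RH", "putamen"):   [50, 15, 5, 67, 75, 37, 61, 75, 46, 75, 42],
    ("LH", "pallidum"):  [35, 1, np.nan, 18, 40, np.nan, 7, 32, np.nan, 45, 7],
    ("RH", "pallidum"):  [40, 13, np.nan, 9, 50, np.nan, 4, 32, 7, 61, 28],
    ("LH", "accumbens"): [np.nan, np.nan, 24, 70, 61, 2, np.nan, np.nan,
                          np.nan, np.nan, np.nan],
    ("RH", "accumbens"): [np.nan, 16, np.nan, 64, 64, 2, np.nan, np.nan,
                          np.nan, 2, np.nan],
}


def detection_counts() -> DetectionMatrix:
    """The published detection-count matrix as a DetectionMatrix."""
    idx = [f"{h} {s}" for (h, s) in _COUNTS]
    df = pd.DataFrame(list(_COUNTS.values()), index=idx, columns=TARGET_REGIONS)
    return DetectionMatrix(df, COHORT_SIZE)


# Two-wave analysis of the 19 qualifying connections: printed annual FA change
# (% per year) and whether the connection was marked significant.
TWO_WAVE_CHANGES = pd.DataFrame(
    [
        ("A", "LH thalamus-SF", 0.17, False),
        ("B", "LH caudate-SF", -0.82, False),
        ("C", "LH putamen-SF", -0.02, False),
        ("D", "LH caudate-MOF", -0.92, True),
        ("E", "RH caudate-MOF", -1.24, True),
        ("F", "LH putamen-MOF", -0.20, False),
        ("G", "LH accumbens-MOF", -0.66, False),
        ("H", "LH caudate-LOF", -1.70, True),
        ("I", "RH caudate-LOF", -2.09, True),
        ("J", "LH putamen-LOF", 0.02, False),
        ("K", "RH putamen-LOF", -1.03, True),
        ("L", "LH putamen-PT", 0.20, False),
        ("M", "RH putamen-PT", -1.03, True),
        ("N", "LH thalamus-RMF", -0.64, False),
        ("O", "RH thalamus-RMF", -1.67, True),
        ("P", "LH caudate-RMF", -1.64, True),
        ("Q", "RH caudate-RMF", -1.56, True),
        ("R", "LH putamen-RMF", -0.04, False),
        ("S", "RH putamen-RMF", -0.91, True),
    ],
    columns=["id", "connection", "pct_change_per_year", "significant"],
)

# Three-wave analysis (N = 24 subsample) of the same 19 connections.
THREE_WAVE_CHANGES = pd.DataFrame(
    [
        ("A", -0.19), ("B", -0.43), ("C", -0.25), ("D", -1.45), ("E", -1.48),
        ("F", -1.11), ("G", -0.28), ("H", -1.71), ("I", -1.71), ("J", -0.46),
        ("K", -0.50), ("L", -0.07), ("M", -0.52), ("N", -0.45), ("O", -1.02),
        ("P", -1.29), ("Q", -1.42), ("R", -0.45), ("S", -0.75),
    ],
    columns=["id", "pct_change_per_year"],
)


def qualifying_connections(fraction: float = 0.9) -> list[tuple[str, str]]:
    """Connections passing the >=ceil(fraction * cohort) detection rule."""
    return cohort_detection_filter(detection_counts(), fraction)


def max_bundles_per_subject() -> int:
    """Seed/target combinatorics: seeds x targets x hemispheres."""
    return len(SEED_REGIONS) * len(TARGET_REGIONS) * len(HEMISPHERES)


def change_magnitude_summary(table: pd.DataFrame,
                             significant_only: bool = False) -> dict[str, float]:
    """Mean/max/min of |annual % FA change| over a printed change table.

    The magnitude convention matches the study's prose summaries (all
    summarized rates share one sign, so signed and magnitude means agree).
    """
    df = table
    if significant_only:
        df = df[df["significant"]]
    mags = df["pct_change_per_year"].abs()
    return {
        "mean": round(float(mags.mean()), 2),
        "max": round(float(mags.max()), 2),
        "min": round(float(mags.min()), 2),
    }
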