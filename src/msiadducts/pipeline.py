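"""End-to-end workflow: preprocess -> blank-subtract -> pairs -> match ->
correlate -> screen, plus scoring against synthetic ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import AdductRegistry, default_registry
from .massdiff import build_pairs, count_by_type, delta_histogram, match_adducts
from .msi_io import IntensityMatrix, PeakList
from .preprocess import (
    BlankReport,
    ToleranceModel,
    filter_frequency,
    filter_intensity,
    filter_topn,
    subtract_blank,
)
from .spatial_stats import apply_screen, correlate_pairs

__all__ = ["PipelineResult", "run_pipeline", "score_against_truth"]


@dataclass
class PipelineResult:
    """Artifacts of a full run."""

    matrix: IntensityMatrix            # after preprocessing + blank subtraction
    total_peaks: int                   # denominator for fractions (pre-subtraction)
    blank_report: BlankReport | None
    pairs: pd.DataFrame                # screened, annotated pair table
    summary: pd.DataFrame              # per-adduct-type counts and fractions
    histogram_top: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_pipeline(
    matrix: IntensityMatrix,
    blank: PeakList | None = None,
    registry: AdductRegistry | None = None,
    tolerance: ToleranceModel | None = None,
    intensity_fraction: float | None = None,
    freq_min: float | None = None,
    top_n: int | None = None,
    screen: str = "rcut",
    alpha: float = 0.05,
    q_cutoff: float = 1e-7,
    r_min: float = 0.1,
    count_unit: str = "distinct_adduct_peaks",
    histogram_binwidth: float = 0.005,
) -> PipelineResult:
    """Run the full adduct-discovery workflow on an intensity matrix.

    The conditioning filters (intensity threshold, pixel-frequency, top-N)
    are opt-in: pass a value to enable one, ``None`` skips it.  Vendor peak
    lists usually arrive already thresholded, and on synthetic data the
    recovery scores are defined over everything that was planted.  The
    per-adduct-type fractions use the post-filter, pre-blank-subtraction peak
    count as denominator.
    """
    registry = registry or default_registry("DHB")
    tolerance = tolerance or ToleranceModel()

    if intensity_fraction is not None:
        matrix = filter_intensity(matrix, intensity_fraction)
    if freq_min is not None:
        matrix = filter_frequency(matrix, freq_min)
    if top_n is not None:
        matrix = filter_topn(matrix, top_n)
    total_peaks = matrix.n_peaks

    blank_report = None
    if blank is not None and blank.n_peaks:
        matrix, blank_report = subtract_blank(matrix, blank, tolerance)

    pairs = build_pairs(matrix.mz) if matrix.n_peaks >= 2 else build_pairs(np.empty(0))
    hist = delta_histogram(pairs, binwidth=histogram_binwidth)
    matched = match_adducts(pairs, registry, tolerance)
    matched = correlate_pairs(matrix, matched)
    screened = apply_screen(matched, screen=screen, alpha=alpha, q_cutoff=q_cutoff, r_min=r_min)
    passing = screened[screened["passed"]]
    summary = count_by_type(passing, max(total_peaks, 1), unit=count_unit)

    return PipelineResult(
        matrix=matrix,
        total_peaks=total_peaks,
        blank_report=blank_report,
        pairs=screened,
        summary=summary,
        histogram_top=hist.top(20),
    )


def score_against_truth(result: PipelineResult, truth, tolerance: ToleranceModel | None = None) -> dict:
    """Sensitivity and precision of the passing pairs against planted pairs.

    A passing pair counts as a true positive when both its masses match a
    planted (parent, adduct) pair within the single-mass tolerance.  Planted
    pairs whose peaks were filtered out upstream still count as misses.
    """
    tolerance = tolerance or ToleranceModel()
    passing = result.pairs[result.pairs["passed"]] if len(result.pairs) else result.pairs
    planted = truth.pairs
    tp = 0
    found = np.zeros(len(planted), dtype=bool)
    for _, row in passing.iterrows():
        tol_p = tolerance.p * row["parent_mz"]
        tol_a = tolerance.p * row["adduct_mz"]
        hit = (
            (np.abs(planted["parent_mz"] - row["parent_mz"]) <= tol_p)
            & (np.abs(planted["adduct_mz"] - row["adduct_mz"]) <= tol_a)
        ).to_numpy()
        if hit.any():
            tp += 1
            found |= hit
    n_pass = len(passing)
    n_truth = len(planted)
    return {
        "n_passing": n_pass,
        "n_planted": n_truth,
        "true_positives": tp,
        "sensitivity": found.sum() / n_truth if n_truth else float("nan"),
        "precision": tp / n_pass if n_pass else float("nan"),
    }
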