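"""Dataset conditioning: ppm tolerances, binning, intensity / frequency / top-N
filters, and matrix-blank subtraction.

All filters operate on an :class:`~msiadducts.msi_io.IntensityMatrix` and are
idempotent; blank subtraction also accepts a plain peak list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .msi_io import IntensityMatrix, PeakList

__all__ = [
    "ToleranceModel",
    "pair_tolerance",
    "single_tolerance",
    "bin_peaks",
    "filter_intensity",
    "filter_frequency",
    "filter_topn",
    "subtract_blank",
    "BlankReport",
]


@dataclass(frozen=True)
class ToleranceModel:
    """Relative mass-accuracy model.

    ``ppm`` is the accuracy p of the processed dataset (5 means 5 ppm).  For a
    mass difference between two measured masses the per-mass uncertainties are
    propagated either in quadrature, p*sqrt(mA^2 + mB^2) (default; standard
    error propagation of two independent ppm-scaled errors), or linearly,
    p*(mA + mB) (strictly more permissive).
    """

    ppm: float = 5.0
    mode: str = "quadrature"

    def __post_init__(self) -> None:
        if self.ppm <= 0:
            raise ValueError("ppm accuracy must be positive")
        if self.mode not in ("quadrature", "linear"):
            raise ValueError(f"unknown tolerance mode {self.mode!r}")

    @property
    def p(self) -> float:
        """Fractional accuracy (ppm / 1e6)."""
        return self.ppm * 1e-6


def pair_tolerance(t: ToleranceModel, mA, mB):
    """Δmass matching tolerance (Da) for a pair of measured masses."""
    mA = np.asarray(mA, dtype=float)
    mB = np.asarray(mB, dtype=float)
    if t.mode == "quadrature":
        return t.p * np.sqrt(mA**2 + mB**2)
    return t.p * (mA + mB)


def single_tolerance(t: ToleranceModel, m):
    """Matching tolerance (Da) around a single measured mass: p * m."""
    return t.p * np.asarray(m, dtype=float)


def _assign_bins(mz: np.ndarray, width: float, relative: bool) -> np.ndarray:
    """Greedy ascending single-linkage cluster labels for a sorted m/z array.

    Two consecutive peaks belong to the same bin when their gap is below the
    width evaluated at the lighter peak (ppm widths scale with m/z).
    """
    if mz.size == 0:
        return np.empty(0, dtype=int)
    gaps = np.diff(mz)
    limits = width * mz[:-1] if relative else np.full(mz.size - 1, width)
    new_bin = gaps >= limits
    return np.concatenate([[0], np.cumsum(new_bin)])


def bin_peaks(m: IntensityMatrix, ppm: float | None = None, mda: float | None = None) -> IntensityMatrix:
    """Merge peaks closer than a bin width (5 ppm or 1 mDa, say).

    Exactly one of ``ppm`` (width scales with m/z) or ``mda`` (absolute width
    in milli-Da) must be given.  Peaks are merged greedily in ascending m/z;
    the merged m/z is the total-intensity-weighted centroid and per-pixel
    intensities are summed, so total intensity per pixel is conserved.
    """
    if (ppm is None) == (mda is None):
        raise ValueError("specify exactly one of ppm or mda")
    if ppm is not None:
        if ppm <= 0:
            raise ValueError("bin width must be positive")
        labels = _assign_bins(m.mz, ppm * 1e-6, relative=True)
    else:
        if mda <= 0:
            raise ValueError("bin width must be positive")
        labels = _assign_bins(m.mz, mda * 1e-3, relative=False)
    if m.n_peaks == 0:
        return m
    n_bins = labels[-1] + 1
    totals = m.values.sum(axis=1)
    weight = np.bincount(labels, weights=totals, minlength=n_bins)
    wsum = np.bincount(labels, weights=m.mz * totals, minlength=n_bins)
    counts = np.bincount(labels, minlength=n_bins)
    plain = np.bincount(labels, weights=m.mz, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        # zero-intensity bins fall back to the unweighted mean position
        new_mz = np.where(weight > 0, wsum / weight, plain / counts)
    new_values = np.zeros((n_bins, m.n_pixels))
    np.add.at(new_values, labels, m.values)
    return IntensityMatrix(new_mz, m.coords, new_values)


def filter_intensity(m: IntensityMatrix, fraction: float = 0.0005, reference: str = "pixel_max") -> IntensityMatrix:
    """Keep peaks whose summary intensity is >= fraction of the dataset maximum.

    With ``reference="pixel_max"`` (default) a peak's summary is its maximum
    single-pixel intensity and the dataset maximum is the global maximum over
    all peaks and pixels; with ``"mean_spectrum"`` both are taken on the mean
    spectrum instead.  Equality is kept.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if m.n_peaks == 0:
        return m
    if reference == "pixel_max":
        summary = m.values.max(axis=1)
    elif reference == "mean_spectrum":
        summary = m.values.mean(axis=1)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return m.take_peaks(summary >= fraction * summary.max())


def filter_frequency(m: IntensityMatrix, min_fraction: float = 0.01) -> IntensityMatrix:
    """Keep peaks detected (nonzero) in at least ceil(min_fraction * n_pixels) pixels."""
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    if m.n_peaks == 0 or min_fraction == 0:
        return m
    need = math.ceil(min_fraction * m.n_pixels)
    return m.take_peaks((m.values > 0).sum(axis=1) >= need)


def filter_topn(m: IntensityMatrix, n: int = 4000) -> IntensityMatrix:
    """Keep the n peaks with the highest total (summed over pixels) intensity.

    Ties are broken in favour of the lower m/z, so the result is deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if m.n_peaks <= n:
        return m
    totals = m.values.sum(axis=1)
    # sort by (-total, mz): lexsort's last key is primary
    order = np.lexsort((m.mz, -totals))
    return m.take_peaks(order[:n])


@dataclass(frozen=True)
class BlankReport:
    """Outcome of matrix-blank subtraction."""

    n_removed: int
    n_kept: int
    removed_mz: np.ndarray       # sample peaks that matched the blank
    matched_blank_mz: np.ndarray  # the nearest blank peak for each removal


def _blank_mask(sample_mz: np.ndarray, blank_mz: np.ndarray, t: ToleranceModel) -> tuple[np.ndarray, np.ndarray]:
    """Boolean removal mask and nearest blank m/z per removed sample peak."""
    if sample_mz.size == 0 or blank_mz.size == 0:
        return np.zeros(sample_mz.size, dtype=bool), np.empty(0)
    idx = np.searchsorted(blank_mz, sample_mz)
    left = np.clip(idx - 1, 0, blank_mz.size - 1)
    right = np.clip(idx, 0, blank_mz.size - 1)
    d_left = np.abs(sample_mz - blank_mz[left])
    d_right = np.abs(sample_mz - blank_mz[right])
    nearest = np.where(d_left <= d_right, blank_mz[left], blank_mz[right])
    tol = single_tolerance(t, sample_mz)
    removed = np.minimum(d_left, d_right) <= tol
    return removed, nearest[removed]


def subtract_blank(sample: IntensityMatrix | PeakList, blank: PeakList, t: ToleranceModel):
    """Remove sample peaks matching a matrix-only (blank) peak list.

    A sample peak is removed when some blank peak lies within
    ``single_tolerance(t, sample_mz)`` of it.  Returns ``(survivor, report)``
    where ``survivor`` has the same type as ``sample``.
    """
    sample_mz = sample.mz
    removed, matched = _blank_mask(sample_mz, blank.mz, t)
    report = BlankReport(
        n_removed=int(removed.sum()),
        n_kept=int((~removed).sum()),
        removed_mz=sample_mz[removed],
        matched_blank_mz=matched,
    )
    if isinstance(sample, IntensityMatrix):
        return sample.take_peaks(~removed), report
    return PeakList(sample.mz[~removed], sample.intensity[~removed]), report
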