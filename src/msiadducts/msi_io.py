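"""MSI data containers and I/O: imzML datasets, CSV intensity matrices, TSV peak lists.

Two containers carry the data through the pipeline:

* :class:`IntensityMatrix` — peaks x pixels intensity table with integer pixel
  coordinates (zeros mean "not detected in that pixel").
* :class:`PeakList` — dataset-level m/z values with one summary intensity each
  (maximum single-pixel intensity by default).

imzML reading/writing delegates to pyimzml; both continuous and processed
(per-pixel axis) centroided files are supported, the latter aligned onto a
common axis by binning.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PeakList",
    "IntensityMatrix",
    "read_imzml",
    "write_imzml",
    "read_intensity_csv",
    "write_intensity_csv",
    "read_peaklist_tsv",
    "write_peaklist_tsv",
    "collapse_to_peaklist",
]


@dataclass(frozen=True)
class PeakList:
    """Sorted m/z values with one non-negative summary intensity each."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.ndim != 1 or inten.shape != mz.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size:
            if np.any(~np.isfinite(mz)) or np.any(mz <= 0):
                raise ValueError("m/z values must be finite and positive")
            if np.any(np.diff(mz) <= 0):
                raise ValueError("m/z values must be strictly increasing")
            if np.any(inten < 0):
                raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    @property
    def n_peaks(self) -> int:
        return self.mz.size


@dataclass(frozen=True)
class IntensityMatrix:
    """Peaks x pixels intensity matrix with 1-based integer pixel coordinates."""

    mz: np.ndarray          # (n_peaks,) strictly increasing
    coords: np.ndarray      # (n_pixels, 2) integer (x, y), unique
    values: np.ndarray      # (n_peaks, n_pixels), all >= 0

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        coords = np.asarray(self.coords, dtype=int)
        values = np.asarray(self.values, dtype=float)
        if mz.size and np.any(np.diff(mz) <= 0):
            raise ValueError("m/z axis must be strictly increasing")
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be (n_pixels, 2)")
        if values.shape != (mz.size, coords.shape[0]):
            raise ValueError(
                f"values shape {values.shape} inconsistent with "
                f"{mz.size} peaks x {coords.shape[0]} pixels"
            )
        if values.size and np.any(values < 0):
            raise ValueError("intensities must be non-negative")
        if len({tuple(c) for c in coords}) != coords.shape[0]:
            raise ValueError("pixel coordinates must be unique")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "values", values)

    @property
    def n_peaks(self) -> int:
        return self.mz.size

    @property
    def n_pixels(self) -> int:
        return self.coords.shape[0]

    def take_peaks(self, index: np.ndarray) -> "IntensityMatrix":
        """New matrix restricted to the given peak indices (kept sorted)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        index = np.sort(index)
        return IntensityMatrix(self.mz[index], self.coords, self.values[index])


def collapse_to_peaklist(m: IntensityMatrix, summary: str = "max") -> PeakList:
    """One summary intensity per peak over pixels (``max``, ``mean`` or ``sum``)."""
    if m.n_peaks == 0:
        return PeakList(np.empty(0), np.empty(0))
    reducers = {"max": np.max, "mean": np.mean, "sum": np.sum}
    try:
        reduce = reducers[summary]
    except KeyError:
        raise ValueError(f"unknown summary {summary!r}: expected max, mean or sum")
    return PeakList(m.mz, reduce(m.values, axis=1))


# --------------------------------------------------------------------------
# CSV intensity matrices: first column m/z, remaining columns named "x<i>_y<j>"
# --------------------------------------------------------------------------

_PIXEL_HEADER = re.compile(r"^x(-?\d+)_y(-?\d+)$")


def write_intensity_csv(m: IntensityMatrix, path: str | Path) -> None:
    cols = [f"x{x}_y{y}" for x, y in m.coords]
    df = pd.DataFrame(m.values, columns=cols)
    df.insert(0, "mz", m.mz)
    df.to_csv(path, index=False, float_format="%.12g")


def read_intensity_csv(path: str | Path, transposed: bool = False) -> IntensityMatrix:
    """Read a peaks x pixels CSV; ``transposed=True`` for pixels x peaks layout."""
    df = pd.read_csv(Path(path), comment="#")
    if transposed:
        df = df.set_index(df.columns[0]).T.reset_index(names="mz")
        df["mz"] = df["mz"].astype(float)
    try:
        mz = df.iloc[:, 0].astype(float).to_numpy()
        values = df.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell: {exc}") from exc
    if np.unique(mz).size != mz.size:
        raise ValueError(f"{path}: duplicate m/z rows; bin the data first")
    coords = []
    synthetic = False
    for i, name in enumerate(df.columns[1:]):
        mobj = _PIXEL_HEADER.match(str(name).strip())
        if mobj:
            coords.append((int(mobj.group(1)), int(mobj.group(2))))
        else:
            synthetic = True
            coords.append((i + 1, 1))
    if synthetic:
        warnings.warn(f"{path}: unparseable pixel headers; assigned sequential coordinates")
        coords = [(i + 1, 1) for i in range(len(coords))]
    order = np.argsort(mz, kind="stable")
    return IntensityMatrix(mz[order], np.array(coords, dtype=int).reshape(-1, 2), values[order])


# --------------------------------------------------------------------------
# TSV peak lists
# --------------------------------------------------------------------------

def write_peaklist_tsv(p: PeakList, path: str | Path) -> None:
    pd.DataFrame({"mz": p.mz, "intensity": p.intensity}).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_peaklist_tsv(path: str | Path) -> PeakList:
    df = pd.read_csv(Path(path), sep="\t", comment="#")
    if not {"mz", "intensity"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'mz' and 'intensity'")
    order = np.argsort(df["mz"].to_numpy(), kind="stable")
    return PeakList(df["mz"].to_numpy()[order], df["intensity"].to_numpy()[order])


# --------------------------------------------------------------------------
# imzML
# --------------------------------------------------------------------------

def write_imzml(m: IntensityMatrix, path: str | Path) -> None:
    """Write a continuous-mode centroided imzML/ibd pair."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = str(path)
    with ImzMLWriter(path, mode="continuous") as writer:
        for j, (x, y) in enumerate(m.coords):
            writer.addSpectrum(m.mz, m.values[:, j], (int(x), int(y), 1))


def read_imzml(path: str | Path, bin_ppm: float = 5.0) -> IntensityMatrix:
    """Read a centroided imzML dataset into an intensity matrix.

    Continuous-mode files map directly onto the shared m/z axis.  In
    processed mode each pixel carries its own axis; spectra are pooled and
    aligned by binning at ``bin_ppm`` (intensity-weighted bin centroids).
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise FileNotFoundError(f"missing binary data file {ibd}")
    parser = ImzMLParser(str(path))
    try:
        mode_tags = set(parser.metadata.file_description.param_by_name)
    except AttributeError:
        mode_tags = set()
    if any("profile" in str(t) for t in mode_tags):
        raise ValueError(f"{path}: profile-mode spectra; centroid the data first")

    n_pixels = len(parser.coordinates)
    coords = np.array([(c[0], c[1]) for c in parser.coordinates], dtype=int)
    spectra = [parser.getspectrum(i) for i in range(n_pixels)]

    axes = [np.asarray(s[0], dtype=float) for s in spectra]
    nonempty = [a for a in axes if a.size]
    continuous = bool(nonempty) and all(
        a.size == nonempty[0].size and np.array_equal(a, nonempty[0]) for a in nonempty
    )
    if continuous:
        mz = nonempty[0]
        values = np.zeros((mz.size, n_pixels))
        for j, (a, inten) in enumerate(spectra):
            if len(a):
                values[:, j] = inten
        order = np.argsort(mz, kind="stable")
        return IntensityMatrix(mz[order], coords, values[order])

    # processed mode: pool (mz, pixel, intensity) triples and bin the axis
    from .preprocess import _assign_bins

    all_mz = np.concatenate([a for a in axes if a.size]) if nonempty else np.empty(0)
    all_int = np.concatenate(
        [np.asarray(s[1], dtype=float) for s in spectra if len(s[0])]
    ) if nonempty else np.empty(0)
    all_pix = np.concatenate(
        [np.full(len(s[0]), j) for j, s in enumerate(spectra) if len(s[0])]
    ) if nonempty else np.empty(0, dtype=int)
    if all_mz.size == 0:
        return IntensityMatrix(np.empty(0), coords, np.empty((0, n_pixels)))
    order = np.argsort(all_mz, kind="stable")
    all_mz, all_int, all_pix = all_mz[order], all_int[order], all_pix[order]
    labels = _assign_bins(all_mz, bin_ppm * 1e-6, relative=True)
    n_bins = labels[-1] + 1
    values = np.zeros((n_bins, n_pixels))
    np.add.at(values, (labels, all_pix.astype(int)), all_int)
    weights = np.bincount(labels, weights=all_int, minlength=n_bins)
    sums = np.bincount(labels, weights=all_mz * all_int, minlength=n_bins)
    counts = np.bincount(labels, minlength=n_bins)
    plain = np.bincount(labels, weights=all_mz, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mz = np.where(weights > 0, sums / weights, plain / counts)
    return IntensityMatrix(mz, coords, values)
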