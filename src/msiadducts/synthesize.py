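"""Seeded synthetic MALDI-MSI generator with ground truth.

Emulates the spatial structure the spatial-correlation screen relies on:

* **parents** — tissue-localized metabolite ions, one smooth 2-D Gaussian
  blob each (random center and width, peak intensity log-uniform over two
  decades);
* **planted adducts** — for each parent and each registry entry planted, a
  peak at parent m/z + registry Δmass whose noise-free image is
  ``yield x parent image``, then degraded by i.i.d. multiplicative log-normal
  pixel noise (log-normal because ion intensities are positive and
  heteroscedastic, and it keeps the expected Pearson r tractable);
* **matrix peaks** — spatially near-uniform background covering the whole
  raster (uniform level + 5% noise), also emitted as the matrix-blank peak
  list;
* **background peaks** — spatially unstructured noise ions: each gets an
  independent i.i.d. log-normal image, so any two of them (and any background/
  parent pair) are uncorrelated in expectation — the null the false-positive
  screens are calibrated against.

All m/z values are drawn within the configured range, kept at least 4x the
jitter scale apart, and jittered by a Gaussian ppm error.  Everything is
reproducible from the seed.

What this deliberately does not model: ion suppression, isotope envelopes
beyond what the registry plants, detector saturation, spatial noise
correlation.  Pipeline results on this generator demonstrate algorithmic
correctness, not instrument-level performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import AdductRegistry, default_registry
from .msi_io import (
    IntensityMatrix,
    PeakList,
    collapse_to_peaklist,
    write_imzml,
    write_intensity_csv,
    write_peaklist_tsv,
)

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "write_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic dataset.

    Defaults describe a small desk-scale raster: 32x32 pixels, 20 parent ions
    each with a DHB-family adduct at 30% yield, 20% multiplicative pixel
    noise, 1 ppm mass jitter, plus uncorrelated background and matrix-cluster
    peaks.
    """

    width: int = 32
    height: int = 32
    n_parents: int = 20
    registry_subset: tuple[str, ...] = ("DHB-H2O",)
    adduct_yield: float = 0.3
    pixel_noise_cv: float = 0.2
    mz_jitter_ppm: float = 1.0
    n_background: int = 40
    n_matrix_peaks: int = 15
    mz_range: tuple[float, float] = (150.0, 900.0)
    intensity_decades: tuple[float, float] = (3.0, 5.0)  # log10 peak intensity
    seed: int = 1

    def __post_init__(self) -> None:
        if min(self.n_parents, self.n_background, self.n_matrix_peaks) < 0:
            raise ValueError("counts must be >= 0")
        if not 0 < self.adduct_yield <= 1:
            raise ValueError("adduct_yield must be in (0, 1]")
        if self.width * self.height < 3:
            raise ValueError("need at least 3 pixels")
        if self.pixel_noise_cv < 0 or self.mz_jitter_ppm < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: adduct pairs, matrix peaks and background peaks."""

    pairs: pd.DataFrame          # parent_mz, adduct_mz, adduct_name (jittered values)
    matrix_mz: np.ndarray
    background_mz: np.ndarray
    parent_mz: np.ndarray = field(default_factory=lambda: np.empty(0))


def _gaussian_blob(rng: np.random.Generator, width: int, height: int) -> np.ndarray:
    """Unit-peak 2-D Gaussian image over the raster, random center and width."""
    x = np.arange(width)[None, :]
    y = np.arange(height)[:, None]
    cx = rng.uniform(0, width - 1)
    cy = rng.uniform(0, height - 1)
    sigma = rng.uniform(max(1.5, width / 12), max(2.0, width / 4))
    return np.exp(-(((x - cx) ** 2) + ((y - cy) ** 2)) / (2 * sigma**2)).ravel()


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log(1.0 + cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def _draw_mz(rng: np.random.Generator, existing: list[float], lo: float, hi: float,
             jitter_ppm: float, max_attempts: int = 100) -> float:
    """Draw an m/z keeping 4x the jitter scale away from all existing peaks."""
    min_sep = 4.0 * max(jitter_ppm, 1.0) * 1e-6 * hi
    for _ in range(max_attempts):
        mz = rng.uniform(lo, hi)
        if all(abs(mz - e) >= min_sep for e in existing):
            return mz
    raise RuntimeError("could not place a collision-free m/z in 100 attempts")


def generate(spec: SyntheticSpec, registry: AdductRegistry | None = None
             ) -> tuple[IntensityMatrix, GroundTruth, PeakList]:
    """Build the synthetic dataset: intensity matrix, ground truth, blank list."""
    rng = np.random.default_rng(spec.seed)
    registry = registry or default_registry("all")
    planted = [registry[name] for name in spec.registry_subset]
    lo, hi = spec.mz_range
    n_pix = spec.width * spec.height
    d_lo, d_hi = spec.intensity_decades

    mz_list: list[float] = []
    images: list[np.ndarray] = []
    truth_rows: list[tuple[float, float, str]] = []
    parent_mzs: list[float] = []
    matrix_mzs: list[float] = []
    background_mzs: list[float] = []

    max_delta = max((e.delta_mass for e in planted), default=0.0)
    min_sep = 4.0 * max(spec.mz_jitter_ppm, 1.0) * 1e-6 * hi
    for _ in range(spec.n_parents):
        # keep room above the parent for its adducts, and make sure the
        # adduct positions are collision-free too
        for _attempt in range(100):
            pmz = _draw_mz(rng, mz_list, lo, hi - max_delta, spec.mz_jitter_ppm)
            adduct_pos = [pmz + e.delta_mass for e in planted]
            if all(abs(a - e) >= min_sep for a in adduct_pos for e in mz_list):
                break
        else:
            raise RuntimeError("could not place a collision-free parent/adduct set")
        amp = 10.0 ** rng.uniform(d_lo, d_hi)
        parent_img = amp * _gaussian_blob(rng, spec.width, spec.height)
        mz_list.append(pmz)
        images.append(parent_img)
        parent_mzs.append(pmz)
        for entry in planted:
            amz = pmz + entry.delta_mass
            adduct_img = spec.adduct_yield * parent_img * _lognormal_noise(
                rng, spec.pixel_noise_cv, n_pix
            )
            mz_list.append(amz)
            images.append(adduct_img)
            truth_rows.append((pmz, amz, entry.name))

    for _ in range(spec.n_matrix_peaks):
        mmz = _draw_mz(rng, mz_list, lo, hi, spec.mz_jitter_ppm)
        amp = 10.0 ** rng.uniform(d_lo, d_hi)
        img = amp * (1.0 + 0.05 * rng.standard_normal(n_pix)).clip(min=0)
        mz_list.append(mmz)
        images.append(img)
        matrix_mzs.append(mmz)

    for _ in range(spec.n_background):
        bmz = _draw_mz(rng, mz_list, lo, hi, spec.mz_jitter_ppm)
        amp = 10.0 ** rng.uniform(d_lo, d_hi)
        mz_list.append(bmz)
        # spatially unstructured: i.i.d. log-normal intensities per pixel
        images.append(amp * rng.lognormal(0.0, 1.0, n_pix))
        background_mzs.append(bmz)

    mz = np.array(mz_list)
    if spec.mz_jitter_ppm > 0:
        jitter = rng.normal(0.0, spec.mz_jitter_ppm * 1e-6, size=mz.size)
        jittered = mz * (1.0 + jitter)
    else:
        jittered = mz.copy()

    # the jittered values are the observed masses; propagate them to the truth
    obs = dict(zip(mz_list, jittered))
    truth = GroundTruth(
        pairs=pd.DataFrame(
            [(obs[p], obs[a], name) for p, a, name in truth_rows],
            columns=["parent_mz", "adduct_mz", "adduct_name"],
        ),
        matrix_mz=np.array([obs[m] for m in matrix_mzs]),
        background_mz=np.array([obs[b] for b in background_mzs]),
        parent_mz=np.array([obs[p] for p in parent_mzs]),
    )

    order = np.argsort(jittered, kind="stable")
    values = np.vstack(images)[order] if images else np.empty((0, n_pix))
    xs, ys = np.meshgrid(np.arange(1, spec.width + 1), np.arange(1, spec.height + 1))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    matrix = IntensityMatrix(jittered[order], coords, values)

    blank_idx = np.searchsorted(matrix.mz, np.sort(truth.matrix_mz))
    blank = PeakList(
        matrix.mz[blank_idx],
        matrix.values[blank_idx].max(axis=1) if blank_idx.size else np.empty(0),
    )
    return matrix, truth, blank


def write_fixture(spec: SyntheticSpec, directory: str | Path,
                  registry: AdductRegistry | None = None) -> dict[str, Path]:
    """Write the dataset to ``directory``: imzML(+ibd), CSV, ground-truth TSV,
    blank TSV.  Returns the paths keyed by role."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    matrix, truth, blank = generate(spec, registry=registry)
    paths = {
        "imzml": directory / "dataset.imzML",
        "csv": directory / "dataset.csv",
        "ground_truth": directory / "ground_truth.tsv",
        "blank": directory / "blank.tsv",
    }
    write_imzml(matrix, paths["imzml"])
    write_intensity_csv(matrix, paths["csv"])
    truth.pairs.to_csv(paths["ground_truth"], sep="\t", index=False)
    write_peaklist_tsv(blank, paths["blank"])
    return paths
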