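"""Reporting: per-adduct-type summary tables, annotated mean spectra, and ion
images.  Every figure has a TSV twin so no number lives only in an image."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .massdiff import count_by_type
from .msi_io import IntensityMatrix

__all__ = ["summarize", "annotate_spectrum", "ion_image", "save_ion_image"]


def summarize(screened: pd.DataFrame, total_peaks: int,
              screens: tuple[str, ...] = ("rcut",)) -> pd.DataFrame:
    """Per-adduct-type summary over one or more screens.

    Rows: ``adduct_name, n_pairs, n_distinct_adduct_peaks,
    fraction_of_total_peaks, screen_used`` — one section per screen, fractions
    counted on distinct adduct peaks against ``total_peaks``.
    """
    sections = []
    for screen in screens:
        col = f"passed_{screen}"
        if col not in screened.columns:
            raise ValueError(f"screen column {col!r} missing; run apply_screen first")
        passing = screened[screened[col]] if len(screened) else screened
        by_pairs = count_by_type(passing, total_peaks, unit="pairs")
        by_peaks = count_by_type(passing, total_peaks, unit="distinct_adduct_peaks")
        merged = by_peaks.rename(columns={"count": "n_distinct_adduct_peaks",
                                          "fraction": "fraction_of_total_peaks"})
        merged["n_pairs"] = by_pairs.set_index("adduct_name")["count"].reindex(
            merged["adduct_name"]).to_numpy() if len(by_pairs) else 0
        merged["screen_used"] = screen
        sections.append(merged[["adduct_name", "n_pairs", "n_distinct_adduct_peaks",
                                "fraction_of_total_peaks", "screen_used"]])
    if not sections:
        raise ValueError("at least one screen required")
    return pd.concat(sections, ignore_index=True)


def annotate_spectrum(m: IntensityMatrix, screened: pd.DataFrame,
                      passed_column: str = "passed") -> pd.DataFrame:
    """Mean spectrum with adduct-member peaks flagged by type.

    Returns a TSV-ready frame ``mz, mean_intensity, adduct_name`` where
    ``adduct_name`` is empty for unflagged peaks and a comma-joined list of
    types for peaks that are the adduct member of at least one passing pair.
    """
    mean_spec = m.values.mean(axis=1) if m.n_pixels else np.zeros(m.n_peaks)
    labels = [""] * m.n_peaks
    if len(screened) and passed_column in screened.columns:
        passing = screened[screened[passed_column]]
        for idx, grp in passing.groupby("adduct_index"):
            labels[int(idx)] = ",".join(sorted(set(grp["adduct_name"])))
    return pd.DataFrame({"mz": m.mz, "mean_intensity": mean_spec, "adduct_name": labels})


def plot_annotated_spectrum(table: pd.DataFrame, path: str | Path) -> None:
    """Render the annotated mean spectrum (stems; flagged peaks highlighted)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3.5))
    flagged = table["adduct_name"].astype(str) != ""
    ax.vlines(table.loc[~flagged, "mz"], 0, table.loc[~flagged, "mean_intensity"],
              colors="0.6", lw=0.8, label="peaks")
    if flagged.any():
        ax.vlines(table.loc[flagged, "mz"], 0, table.loc[flagged, "mean_intensity"],
                  colors="crimson", lw=1.2, label="adduct peaks")
    ax.set_xlabel("m/z")
    ax.set_ylabel("mean intensity")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ion_image(m: IntensityMatrix, mz: float, tol_ppm: float = 2.5) -> np.ndarray:
    """Per-pixel summed intensity of all peaks within ±tol_ppm of ``mz``.

    Returned as a (height, width) array on the raster grid; pixels absent
    from the raster are NaN.  No interpolation is applied.
    """
    if not (m.mz.size and m.mz[0] <= mz <= m.mz[-1]):
        warnings.warn(f"m/z {mz} outside the dataset axis; image is all zero")
    tol = tol_ppm * 1e-6 * mz
    sel = np.abs(m.mz - mz) <= tol
    if not sel.any():
        warnings.warn(f"no peak within ±{tol_ppm} ppm of m/z {mz}")
        per_pixel = np.zeros(m.n_pixels)
    else:
        per_pixel = m.values[sel].sum(axis=0)
    xs, ys = m.coords[:, 0], m.coords[:, 1]
    img = np.full((ys.max() - ys.min() + 1, xs.max() - xs.min() + 1), np.nan)
    img[ys - ys.min(), xs - xs.min()] = per_pixel
    return img


def save_ion_image(m: IntensityMatrix, mz: float, path: str | Path,
                   tol_ppm: float = 2.5, cmap: str = "viridis") -> np.ndarray:
    """Render an ion image to PNG/SVG alongside a TSV twin of the pixel values."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = ion_image(m, mz, tol_ppm=tol_ppm)
    path = Path(path)
    pd.DataFrame(img).to_csv(path.with_suffix(".tsv"), sep="\t", index=False, header=False)
    fig, ax = plt.subplots()
    im = ax.imshow(img, origin="lower", cmap=cmap, interpolation="none")
    fig.colorbar(im, ax=ax, label="intensity")
    ax.set_title(f"m/z {mz:.4f} (±{tol_ppm} ppm)")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return img
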