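"""All-pairs mass-difference analysis: pair building, Δmass histograms, and
adduct-registry matching.

The method rests on a simple observation: an adduct ion appears at a
characteristic mass offset above its parent ion (e.g. +21.982 for Na-for-H,
+136.016 for a DHB matrix molecule that lost water).  Computing the mass
difference for every unordered pair of peaks and histogramming those Δmass
values makes abundant adduct chemistries stand out as crowded histogram bins;
matching the pairs against a registry of known offsets, within a
ppm-propagated tolerance, yields candidate parent/adduct pairs.

Pairs live in a "pair table": a pandas DataFrame with columns
``parent_index, adduct_index, parent_mz, adduct_mz, delta`` oriented
heavier-minus-lighter, extended by matching with
``adduct_name, registry_delta, error_da, error_ppm, ambiguous``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .chem import AdductRegistry
from .msi_io import PeakList
from .preprocess import ToleranceModel, pair_tolerance

__all__ = [
    "PAIR_COLUMNS",
    "build_pairs",
    "iter_pair_chunks",
    "DeltaHistogram",
    "delta_histogram",
    "match_adducts",
    "count_by_type",
]

PAIR_COLUMNS = ["parent_index", "adduct_index", "parent_mz", "adduct_mz", "delta"]


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=int if c.endswith("index") else float)
                         for c in PAIR_COLUMNS})


def iter_pair_chunks(mz: np.ndarray, chunk_rows: int = 2_000_000) -> Iterator[pd.DataFrame]:
    """Yield the all-pairs table in chunks of at most ``chunk_rows`` rows.

    The full table has n(n-1)/2 rows; chunked generation keeps peak counts of
    10^4 (~5x10^7 pairs) workable without materializing everything at once.
    Chunks come out ordered by (parent_mz, adduct_mz).
    """
    mz = np.asarray(mz, dtype=float)
    n = mz.size
    buf: list[pd.DataFrame] = []
    buffered = 0
    for i in range(n - 1):
        j = np.arange(i + 1, n)
        block = pd.DataFrame(
            {
                "parent_index": np.full(j.size, i),
                "adduct_index": j,
                "parent_mz": np.full(j.size, mz[i]),
                "adduct_mz": mz[j],
                "delta": mz[j] - mz[i],
            }
        )
        buf.append(block)
        buffered += len(block)
        if buffered >= chunk_rows:
            yield pd.concat(buf, ignore_index=True)
            buf, buffered = [], 0
    if buf:
        yield pd.concat(buf, ignore_index=True)


def build_pairs(peaks: PeakList | np.ndarray) -> pd.DataFrame:
    """All unordered peak pairs, oriented heavier-minus-lighter.

    Exactly n(n-1)/2 rows for n peaks, ordered by (parent_mz, adduct_mz).
    With fewer than 2 peaks an empty table is returned with a warning.
    """
    mz = peaks.mz if isinstance(peaks, PeakList) else np.asarray(peaks, dtype=float)
    if mz.size < 2:
        warnings.warn("fewer than 2 peaks: empty pair table")
        return _empty_pairs()
    iu, ju = np.triu_indices(mz.size, k=1)
    return pd.DataFrame(
        {
            "parent_index": iu,
            "adduct_index": ju,
            "parent_mz": mz[iu],
            "adduct_mz": mz[ju],
            "delta": mz[ju] - mz[iu],
        }
    )


@dataclass(frozen=True)
class DeltaHistogram:
    """Fixed-width histogram of pair mass differences starting at 0 Da."""

    edges: np.ndarray   # (n_bins + 1,)
    counts: np.ndarray  # (n_bins,)
    binwidth: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def top(self, k: int = 10) -> pd.DataFrame:
        """The k most populated bins: columns ``center, count`` by count desc."""
        order = np.lexsort((self.centers, -self.counts))[:k]
        return pd.DataFrame({"center": self.centers[order], "count": self.counts[order]})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.centers, "count": self.counts})


def delta_histogram(pairs: pd.DataFrame, binwidth: float = 0.005) -> DeltaHistogram:
    """Histogram the ``delta`` column with fixed-width bins from 0 to max(delta)."""
    if binwidth <= 0:
        raise ValueError("binwidth must be positive")
    deltas = pairs["delta"].to_numpy() if len(pairs) else np.empty(0)
    if deltas.size == 0:
        return DeltaHistogram(np.array([0.0, binwidth]), np.zeros(1, dtype=int), binwidth)
    n_bins = int(np.floor(deltas.max() / binwidth)) + 1
    edges = np.arange(n_bins + 1) * binwidth
    counts, _ = np.histogram(deltas, bins=edges)
    return DeltaHistogram(edges, counts, binwidth)


def match_adducts(pairs: pd.DataFrame, registry: AdductRegistry, t: ToleranceModel) -> pd.DataFrame:
    """Keep pairs whose Δmass matches a registry entry within the pair tolerance.

    A row matches entry E when ``|delta - E.delta_mass| <= pair_tolerance(t,
    parent_mz, adduct_mz)``.  Rows matching several entries are emitted once
    per entry with ``ambiguous=True``.  Annotations: ``adduct_name,
    adduct_category, registry_delta, error_da`` (signed, observed minus
    registry) and ``error_ppm`` (relative to the adduct mass).
    """
    if len(registry) == 0:
        raise ValueError("empty adduct registry")
    if len(pairs) == 0:
        out = _empty_pairs()
        for col, dtype in [("adduct_name", object), ("adduct_category", object),
                           ("registry_delta", float), ("error_da", float),
                           ("error_ppm", float), ("ambiguous", bool)]:
            out[col] = pd.Series(dtype=dtype)
        return out
    delta = pairs["delta"].to_numpy()
    tol = pair_tolerance(t, pairs["parent_mz"].to_numpy(), pairs["adduct_mz"].to_numpy())
    matched_blocks = []
    for entry in registry:
        err = delta - entry.delta_mass
        hit = np.abs(err) <= tol
        if not hit.any():
            continue
        block = pairs.loc[hit].copy()
        block["adduct_name"] = entry.name
        block["adduct_category"] = entry.category
        block["registry_delta"] = entry.delta_mass
        block["error_da"] = err[hit]
        block["error_ppm"] = err[hit] / block["adduct_mz"].to_numpy() * 1e6
        matched_blocks.append(block)
    if not matched_blocks:
        return match_adducts(_empty_pairs(), registry, t)
    out = pd.concat(matched_blocks, ignore_index=True)
    dup = out.duplicated(subset=["parent_index", "adduct_index"], keep=False)
    out["ambiguous"] = dup
    return out.sort_values(["parent_mz", "adduct_mz", "adduct_name"], ignore_index=True)


def count_by_type(matched: pd.DataFrame, total_peaks: int, unit: str = "distinct_adduct_peaks") -> pd.DataFrame:
    """Per-adduct-type counts and fractions of the total peak count.

    ``unit="distinct_adduct_peaks"`` (default) counts, per adduct type, the
    distinct peaks that appear as the adduct member of at least one row;
    ``unit="pairs"`` counts rows.  Fractions are count / total_peaks.
    """
    if total_peaks < 1:
        raise ValueError("total_peaks must be >= 1")
    if unit not in ("distinct_adduct_peaks", "pairs"):
        raise ValueError(f"unknown counting unit {unit!r}")
    if len(matched) == 0:
        return pd.DataFrame({"adduct_name": pd.Series(dtype=object),
                             "count": pd.Series(dtype=int),
                             "fraction": pd.Series(dtype=float)})
    if unit == "pairs":
        counts = matched.groupby("adduct_name", sort=True).size()
    else:
        counts = matched.groupby("adduct_name", sort=True)["adduct_index"].nunique()
    out = counts.rename("count").reset_index()
    out["fraction"] = out["count"] / total_peaks
    return out
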