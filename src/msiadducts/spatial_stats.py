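"""Spatial false-positive control for candidate parent/adduct pairs.

A genuine adduct forms wherever its parent ion is abundant, so the two ion
images should be positively correlated across pixels.  Each candidate pair
gets a Pearson correlation over per-pixel intensities (zeros included: pixels
where a peak was not detected are true zeros, and co-absence is spatial
information) and a two-sided p-value from the exact t transform
``t = r * sqrt((n-2) / (1-r^2))`` with n-2 degrees of freedom.  Three screens
are offered:

* Bonferroni — reject when ``min(1, m*p) >= alpha`` (default alpha 0.05);
* Storey q-values on the positively-correlated pairs (default cutoff 1e-7);
* a direct correlation-coefficient cutoff, ``r > r_min`` strictly.

All screens additionally require positive correlation: co-localization, not
mere dependence, is the signature being tested.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .msi_io import IntensityMatrix

__all__ = [
    "correlate_pairs",
    "bonferroni",
    "qvalues",
    "estimate_pi0",
    "filter_correlation",
    "apply_screen",
    "SCREENS",
]

SCREENS = ("bonferroni", "qvalue", "rcut")


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r between paired 2-D arrays; NaN for constant rows."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def correlate_pairs(m: IntensityMatrix, pairs: pd.DataFrame, nonzero_only: bool = False) -> pd.DataFrame:
    """Annotate a pair table with Pearson ``r``, two-sided ``p`` and ``n_pixels``.

    By default the correlation runs over every pixel of the raster.  With
    ``nonzero_only=True`` each pair is restricted to pixels where at least one
    of the two peaks was detected.  Constant intensity vectors have undefined
    correlation: ``r`` is reported as NaN with ``p = 1``.
    """
    if m.n_pixels < 3:
        raise ValueError("correlation test undefined for fewer than 3 pixels")
    out = pairs.copy()
    if len(pairs) == 0:
        out["r"] = pd.Series(dtype=float)
        out["p"] = pd.Series(dtype=float)
        out["n_pixels"] = pd.Series(dtype=int)
        return out
    pi = pairs["parent_index"].to_numpy()
    ai = pairs["adduct_index"].to_numpy()
    if not nonzero_only:
        a, b = m.values[pi], m.values[ai]
        r = _pearson_rows(a, b)
        n = np.full(len(pairs), m.n_pixels)
    else:
        r = np.empty(len(pairs))
        n = np.empty(len(pairs), dtype=int)
        for k in range(len(pairs)):
            x, y = m.values[pi[k]], m.values[ai[k]]
            mask = (x > 0) | (y > 0)
            n[k] = mask.sum()
            r[k] = _pearson_rows(x[mask][None, :], y[mask][None, :])[0] if n[k] >= 3 else np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=np.maximum(n - 2, 1))
    p[np.isnan(r)] = 1.0
    p[np.abs(r) == 1.0] = 0.0  # degenerate t -> inf
    out["r"], out["p"], out["n_pixels"] = r, p, n
    return out


def bonferroni(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni screen: ``p_bonferroni = min(1, m*p)``; pass needs
    ``p_bonferroni < alpha`` and positive correlation."""
    out = results.copy()
    m = len(results)
    p = results["p"].to_numpy() if m else np.empty(0)
    pb = np.minimum(1.0, m * p)
    out["p_bonferroni"] = pb
    out["passed_bonferroni"] = (pb < alpha) & (results["r"].to_numpy() > 0 if m else True)
    return out


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey estimate of the null proportion pi0.

    ``pi0(lambda) = #{p > lambda} / (m * (1 - lambda))`` is computed on a
    lambda grid (default 0.05..0.95 step 0.05) and extrapolated to lambda = 1
    with a cubic polynomial smoother; the result is clipped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    if p.size < 10:
        warnings.warn("fewer than 10 p-values: pi0 fixed at 1")
        return 1.0
    m = p.size
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coef, 1.0))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def qvalues(p: np.ndarray | pd.Series, pi0: float | None = None) -> np.ndarray:
    """Storey q-values for a vector of p-values.

    ``q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j)``; with
    ``pi0 = 1`` this is exactly the Benjamini-Hochberg step-up adjustment.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def add_qvalues(results: pd.DataFrame, cutoff: float = 1e-7, pi0: float | None = None) -> pd.DataFrame:
    """q-value screen on the pair table; pass needs ``q < cutoff`` and r > 0.

    As in FDR practice for co-localization, pi0 is estimated from (and q-values
    assigned to) the positively correlated pairs only; non-positive pairs get
    q = 1.
    """
    out = results.copy()
    q = np.ones(len(results))
    pos = results["r"].to_numpy() > 0 if len(results) else np.empty(0, dtype=bool)
    if pos.any():
        q[pos] = qvalues(results.loc[pos, "p"].to_numpy(), pi0=pi0)
    out["q"] = q
    out["passed_qvalue"] = (q < cutoff) & pos
    return out


def filter_correlation(results: pd.DataFrame, r_min: float = 0.1) -> pd.DataFrame:
    """Direct cutoff screen: pass needs ``r > r_min`` strictly (NaN fails)."""
    out = results.copy()
    r = results["r"].to_numpy() if len(results) else np.empty(0)
    with np.errstate(invalid="ignore"):
        out["passed_rcut"] = r > r_min
    return out


def apply_screen(results: pd.DataFrame, screen: str = "rcut", alpha: float = 0.05,
                 q_cutoff: float = 1e-7, r_min: float = 0.1) -> pd.DataFrame:
    """Compute all three screens and set ``passed`` from the chosen one."""
    if screen not in SCREENS:
        raise ValueError(f"unknown screen {screen!r}: expected one of {SCREENS}")
    out = bonferroni(results, alpha=alpha)
    out = add_qvalues(out, cutoff=q_cutoff)
    out = filter_correlation(out, r_min=r_min)
    out["passed"] = out[f"passed_{screen}"]
    return out
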