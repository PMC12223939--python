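"""Aggregation indices condensed from monthly prediction fields.

Two complementary interannual indices are derived from a stack of
monthly-mean aggregation-probability maps (one map per year for a given
calendar month):

* the leading principal component of an EOF decomposition of the
  year × cell anomaly matrix — the dominant interannual mode of the
  field, with the mode sign fixed so the PC tracks the domain-mean
  anomaly non-negatively;
* a hotspot-area index — the number of grid cells exceeding the pooled
  climatological mean + 2 SD, counted per year and normalized to zero
  mean / unit SD.

Agreement between the two (Spearman rank correlation) is the internal
consistency check of the analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EOFResult:
    """EOF decomposition of a year × cell anomaly matrix.

    ``modes`` holds the orthonormal spatial patterns (n_modes, n_cells);
    ``pcs`` the unit-variance principal-component series (n_years,
    n_modes); ``explained_variance`` the variance fraction per mode.
    ``valid_cells`` indexes the columns retained (cells with no missing
    year); ``shape`` allows reshaping modes back to maps.
    """

    modes: np.ndarray
    pcs: np.ndarray
    explained_variance: np.ndarray
    years: np.ndarray
    valid_cells: np.ndarray
    shape: tuple | None = None

    def mode_map(self, k: int = 0) -> np.ndarray:
        if self.shape is None:
            raise ValueError("no map shape recorded")
        out = np.full(int(np.prod(self.shape)), np.nan)
        out[self.valid_cells] = self.modes[k]
        return out.reshape(self.shape)

    def pc(self, k: int = 0) -> "IndexSeries":
        return IndexSeries(
            years=self.years, values=self.pcs[:, k], provenance="EOF_PC1" if k == 0 else f"EOF_PC{k+1}"
        )


@dataclass
class IndexSeries:
    """Normalized annual index (zero mean, unit SD over available years)."""

    years: np.ndarray
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.years) != len(self.values):
            raise ValueError("years and values must align")


def eof_decompose(stack: np.ndarray, years, map_shape: tuple | None = None) -> EOFResult:
    """EOF/PC decomposition by SVD of the demeaned year × cell matrix.

    Cells with any missing (NaN) year are dropped (recorded in
    ``valid_cells``); the per-cell temporal mean is removed; modes are
    right singular vectors, PCs are scaled to unit variance, and each
    mode's sign is chosen so its PC correlates non-negatively with the
    domain-mean anomaly series.
    """
    X = np.asarray(stack, dtype=float)
    if X.ndim > 2:
        map_shape = X.shape[1:]
        X = X.reshape(X.shape[0], -1)
    years = np.asarray(years)
    if X.shape[0] < 3:
        raise ValueError("EOF needs at least 3 years")
    valid = np.flatnonzero(np.isfinite(X).all(axis=0))
    if valid.size == 0:
        raise ValueError("no cell has a complete year record")
    X = X[:, valid]
    anom = X - X.mean(axis=0, keepdims=True)
    if not np.any(np.abs(anom) > 0):
        raise ValueError("field has zero variance; EOF undefined")
    U, s, Vt = np.linalg.svd(anom, full_matrices=False)
    pcs = U * s  # raw amplitude
    domain_mean = anom.mean(axis=1)
    n_modes = len(s)
    for k in range(n_modes):
        if pcs[:, k].std() > 0:
            r = np.corrcoef(pcs[:, k], domain_mean)[0, 1]
            if np.isfinite(r) and r < 0:
                pcs[:, k] *= -1
                Vt[k] *= -1
    sd = pcs.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    pcs_unit = pcs / sd
    ev = s**2 / np.sum(s**2)
    return EOFResult(
        modes=Vt, pcs=pcs_unit, explained_variance=ev, years=years,
        valid_cells=valid, shape=map_shape,
    )


def hotspot_area_index(stack: np.ndarray, years, k_sd: float = 2.0) -> IndexSeries:
    """Normalized count of cells exceeding the pooled mean + k·SD.

    The threshold is computed over the pooled cell-year values of the
    stack (the field's climatology); per year, cells strictly above the
    threshold are counted, and the counts are normalized to zero mean and
    unit SD across years.
    """
    X = np.asarray(stack, dtype=float)
    X = X.reshape(X.shape[0], -1)
    if X.shape[0] < 3:
        raise ValueError("hotspot index needs at least 3 years")
    pooled = X[np.isfinite(X)]
    if pooled.std() == 0:
        raise ValueError("field has zero variance; hotspot threshold undefined")
    thr = pooled.mean() + k_sd * pooled.std()
    counts = np.nansum(X > thr, axis=1).astype(float)
    sd = counts.std()
    if sd == 0:
        values = counts - counts.mean()
    else:
        values = (counts - counts.mean()) / sd
    return IndexSeries(years=np.asarray(years), values=values, provenance="hotspot_area")


def _std_ranks(x: np.ndarray) -> np.ndarray:
    r = stats.rankdata(x)
    return (r - r.mean()) / r.std()


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (small n).

    Enumerates all n! orderings of one rank vector, in chunks to bound
    memory.
    """
    rx, ry = _std_ranks(x), _std_ranks(y)
    n = len(rx)
    obs = abs(rho)
    count = total = 0
    chunk: list = []
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            r = rx[np.array(chunk)] @ ry / n
            count += int(np.sum(np.abs(r) >= obs - 1e-12))
            total += len(chunk)
            chunk = []
    if chunk:
        r = rx[np.array(chunk)] @ ry / n
        count += int(np.sum(np.abs(r) >= obs - 1e-12))
        total += len(chunk)
    return count / total


def spearman_permutation_p(x, y, n_perm: int = 2000, seed: int = 0) -> float:
    """Two-sided Monte-Carlo permutation p-value for Spearman rho."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx, ry = _std_ranks(x), _std_ranks(y)
    n = len(rx)
    obs = abs(float(np.mean(rx * ry)))
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    r = rx[perms] @ ry / n
    return float((1 + np.sum(np.abs(r) >= obs - 1e-12)) / (1 + n_perm))


def spearman(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    Uses the t-approximation, except for n ≤ ``exact_max_n`` where the
    exact permutation distribution of the rank correlation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho, p_t = stats.spearmanr(x, y)
    if len(x) <= exact_max_n:
        return float(rho), _spearman_exact_p(x, y, rho)
    return float(rho), float(p_t)


def compare_indices(a: IndexSeries, b: IndexSeries) -> tuple[float, float]:
    """Spearman rank agreement between two annual indices.

    Correlates the two series over their overlapping years; requires at
    least 5 overlapping years.
    """
    common, ia, ib = np.intersect1d(a.years, b.years, return_indices=True)
    if len(common) < 5:
        raise ValueError(f"only {len(common)} overlapping years; need >= 5")
    return spearman(a.values[ia], b.values[ib])
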