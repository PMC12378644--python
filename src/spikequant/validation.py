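"""Comparison statistics between quantification methods.

Paired slope/correlation against an independent reference (e.g. flow
cytometry or simulation truth), fold-range across stations, microscopy
filament-to-cell conversion, relative-abundance derivation, and
Bray-Curtis dissimilarity with classical PCoA variance explained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

SLOPE_MODELS = ("origin", "ols", "sma", "all")
EIGEN_CORRECTIONS = ("clip", "lingoes")


@dataclass
class PairedSeries:
    """Paired reference (x) vs estimate (y) values keyed by sample."""

    sample_ids: list[str]
    x: np.ndarray
    y: np.ndarray
    transform: str = "linear"  # or "log10"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.sample_ids) == len(self.x) == len(self.y)):
            raise ValueError("sample_ids, x and y must have equal lengths")
        if self.transform not in ("linear", "log10"):
            raise ValueError("transform must be 'linear' or 'log10'")
        if self.transform == "log10" and ((self.x <= 0).any() or (self.y <= 0).any()):
            raise ValueError("log10 transform requires positive values")

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass
class ComparisonStats:
    slopes: dict[str, float]  # keyed by slope model
    pearson_r: float
    n: int


def _slope(x: np.ndarray, y: np.ndarray, model: str) -> float:
    if model == "origin":
        return float(np.dot(x, y) / np.dot(x, x))
    if model == "ols":
        return float(np.polyfit(x, y, 1)[0])
    if model == "sma":
        r = np.corrcoef(x, y)[0, 1]
        return float(np.sign(r) * np.std(y, ddof=1) / np.std(x, ddof=1))
    raise ValueError(f"unknown slope model {model!r}")


def paired_comparison(series: PairedSeries, slope_model: str = "origin") -> ComparisonStats:
    """Pearson r and slope(s) for a paired series.

    Default slope model is OLS through the origin on the (optionally
    log10-transformed) values, so a slope near 1 means numeric
    equivalence of counts; ``slope_model='all'`` reports every variant.
    """
    if slope_model not in SLOPE_MODELS:
        raise ValueError(f"slope_model must be one of {SLOPE_MODELS}")
    if series.n < 3:
        raise ValueError("need at least 3 pairs")
    x, y = series.x, series.y
    if series.transform == "log10":
        x, y = np.log10(x), np.log10(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    models = ("origin", "ols", "sma") if slope_model == "all" else (slope_model,)
    slopes = {m: _slope(x, y, m) for m in models}
    r = float(stats.pearsonr(x, y).statistic)
    return ComparisonStats(slopes=slopes, pearson_r=r, n=len(x))


def fold_range(values) -> float:
    """max / min of a positive series (e.g. across-station variation)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty series")
    if (v <= 0).any():
        raise ValueError("fold_range undefined for non-positive values")
    return float(v.max() / v.min())


def filaments_to_cells(filaments_per_liter: float, cells_per_filament: float = 100.0) -> float:
    """Convert filament counts to cell counts (default 100 cells/filament)."""
    if filaments_per_liter < 0 or cells_per_filament < 0:
        raise ValueError("inputs must be >= 0")
    return filaments_per_liter * cells_per_filament


def relative_from_absolute(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Row-normalize a samples x taxa abundance matrix to proportions."""
    values = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    sums = values.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("every sample row must have a positive total")
    rel = values / sums[:, None]
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(rel, index=matrix.index, columns=matrix.columns)
    return rel


def braycurtis_matrix(matrix: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity, sum|x-y| / sum(x+y)."""
    values = np.asarray(matrix, dtype=float)
    if (values < 0).any():
        raise ValueError("matrix must be non-negative")
    if (values.sum(axis=1) <= 0).any():
        raise ValueError("all-zero sample row")
    return squareform(pdist(values, metric="braycurtis"))


def pcoa_variance_explained(
    dissimilarity: np.ndarray, n_axes: int = 2, correction: str = "clip"
) -> tuple[np.ndarray, float]:
    """Classical metric MDS of a dissimilarity matrix.

    Returns (eigenvalues, fraction of positive eigenvalue mass on the
    first ``n_axes`` axes). Negative eigenvalues from non-Euclidean
    dissimilarities are clipped at zero by default; ``lingoes`` adds the
    constant that makes the matrix Euclidean instead.
    """
    if correction not in EIGEN_CORRECTIONS:
        raise ValueError(f"correction must be one of {EIGEN_CORRECTIONS}")
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("dissimilarity matrix must be square")

    def _eigvals(dmat: np.ndarray) -> np.ndarray:
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (dmat**2) @ j
        return np.linalg.eigvalsh(b)[::-1]

    eig = _eigvals(d)
    if correction == "lingoes" and eig[-1] < 0:
        c = -eig[-1]
        d2 = np.sqrt(d**2 + 2 * c)
        np.fill_diagonal(d2, 0.0)
        eig = _eigvals(d2)
    pos = np.clip(eig, 0.0, None)
    total = pos.sum()
    if total == 0:
        raise ValueError("degenerate dissimilarity matrix (all samples identical)")
    frac = float(pos[:n_axes].sum() / total)
    return eig, frac


def braycurtis_pcoa(
    matrix: pd.DataFrame | np.ndarray,
    mode: str = "relative",
    n_axes: int = 2,
    correction: str = "clip",
) -> tuple[np.ndarray, float]:
    """Bray-Curtis dissimilarity + PCoA variance on the first axes.

    ``mode='relative'`` row-normalizes the abundance matrix first (the
    compositional view); ``mode='absolute'`` ordinates raw abundances.
    Needs at least 3 samples.
    """
    if mode not in ("relative", "absolute"):
        raise ValueError("mode must be 'relative' or 'absolute'")
    values = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if mode == "relative":
        values = relative_from_absolute(values)
    d = braycurtis_matrix(values)
    _, frac = pcoa_variance_explained(d, n_axes=n_axes, correction=correction)
    return d, frac
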