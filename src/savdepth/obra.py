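"""Optimal Band Ratio Analysis (OBRA).

Under the shallow clear-water model, upwelling radiance decays
exponentially with submergence depth d at a wavelength-dependent rate
K(lambda).  The log band ratio

    X = ln(L1 / L2)

is then linear in d with slope K2 - K1, regardless of absolute
radiometric calibration.  OBRA exhaustively regresses X on d over every
wavelength pair and reports the coefficient of determination, regression
coefficients and slope significance in n x n matrices, from which the
best-performing pair is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import SpectralLibrary

__all__ = [
    "OBRAResult",
    "compute_X",
    "obra_matrix",
    "significance_mask",
    "best_ratio",
    "export_matrix",
    "read_matrix",
    "plot_obra_matrix",
]


@dataclass
class OBRAResult:
    """Per-band-pair regression results of X = ln(L1/L2) on depth.

    Matrices are indexed [i, j] for numerator wavelength i and denominator
    wavelength j: r2 is symmetric, slope antisymmetric, and the diagonal
    (X identically zero) is NaN-flagged.
    """

    wavelengths: np.ndarray
    r2: np.ndarray
    slope: np.ndarray
    intercept: np.ndarray
    pvalue: np.ndarray
    n_obs: np.ndarray  # valid samples per cell

    def __post_init__(self) -> None:
        n = self.wavelengths.size
        for name in ("r2", "slope", "intercept", "pvalue", "n_obs"):
            m = getattr(self, name)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size


def compute_X(values1, values2) -> np.ndarray:
    """X = ln(values1 / values2), elementwise, for strictly positive inputs."""
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("values1 and values2 must have the same shape")
    bad = np.flatnonzero((v1 <= 0) | (v2 <= 0))
    if bad.size:
        raise ValueError(
            f"nonpositive values at indices {bad[:10].tolist()}; exclude or "
            "flag these samples before computing X"
        )
    return np.log(v1) - np.log(v2)


def _pair_stats_from_moments(c_zd, C_zz, var_d, mean_z, mean_d, n):
    """Vectorised OLS of X_ij = z_i - z_j on d from first/second moments."""
    ns = c_zd.size
    slope = (c_zd[:, None] - c_zd[None, :]) / var_d
    intercept = (mean_z[:, None] - mean_z[None, :]) - slope * mean_d
    var_x = C_zz.diagonal()[:, None] + C_zz.diagonal()[None, :] - 2.0 * C_zz
    cov_xd = c_zd[:, None] - c_zd[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = cov_xd**2 / (var_x * var_d)
        r2 = np.where(var_x > 0, r2, np.nan)
        # guard numerical overshoot of exact fits
        r2 = np.clip(r2, 0.0, 1.0)
        tsq = r2 * (n - 2) / (1.0 - r2)
    pvalue = 2.0 * stats.t.sf(np.sqrt(tsq), df=n - 2)
    pvalue = np.where(np.isnan(r2), np.nan, np.where(np.isinf(tsq), 0.0, pvalue))
    np.fill_diagonal(slope, 0.0)
    np.fill_diagonal(intercept, 0.0)
    for m in (slope, intercept, r2, pvalue):
        np.fill_diagonal(m, np.nan)
    return r2, slope, intercept, pvalue


def obra_matrix(library: SpectralLibrary) -> OBRAResult:
    """Regress X on depth for every wavelength pair of the library.

    Samples with nonpositive values at a pair are dropped pairwise
    (ln is undefined there); cells left with fewer than 3 valid samples
    are flagged NaN rather than zero.
    """
    values = library.values
    depths = library.depths
    n_samples, n_bands = values.shape
    if n_samples < 3:
        raise ValueError("OBRA needs at least 3 samples")
    var_d = np.var(depths)
    if var_d == 0:
        warnings.warn("zero depth variance: all OBRA cells undefined", stacklevel=2)
        nanm = np.full((n_bands, n_bands), np.nan)
        return OBRAResult(
            library.wavelengths, nanm.copy(), nanm.copy(), nanm.copy(), nanm.copy(),
            np.full((n_bands, n_bands), n_samples),
        )

    if np.all(values > 0):
        z = np.log(values)
        dc = depths - depths.mean()
        c_zd = z.T @ dc / n_samples
        C_zz = np.cov(z, rowvar=False, bias=True)
        r2, slope, intercept, pvalue = _pair_stats_from_moments(
            c_zd, np.atleast_2d(C_zz), dc @ dc / n_samples, z.mean(axis=0),
            depths.mean(), n_samples,
        )
        n_obs = np.full((n_bands, n_bands), n_samples)
        return OBRAResult(library.wavelengths, r2, slope, intercept, pvalue, n_obs)

    # slow path: pairwise-complete exclusion of nonpositive samples
    r2 = np.full((n_bands, n_bands), np.nan)
    slope = np.full_like(r2, np.nan)
    intercept = np.full_like(r2, np.nan)
    pvalue = np.full_like(r2, np.nan)
    n_obs = np.zeros((n_bands, n_bands), dtype=int)
    pos = values > 0
    for i in range(n_bands):
        for j in range(i):
            keep = pos[:, i] & pos[:, j]
            n_obs[i, j] = n_obs[j, i] = keep.sum()
            if keep.sum() < 3 or np.var(depths[keep]) == 0:
                continue
            x = np.log(values[keep, i]) - np.log(values[keep, j])
            res = stats.linregress(depths[keep], x)
            r2[i, j] = r2[j, i] = res.rvalue**2
            slope[i, j] = res.slope
            slope[j, i] = -res.slope
            intercept[i, j] = res.intercept
            intercept[j, i] = -res.intercept
            pvalue[i, j] = pvalue[j, i] = res.pvalue
    return OBRAResult(library.wavelengths, r2, slope, intercept, pvalue, n_obs)


def significance_mask(result: OBRAResult, levels: Sequence[float] = (0.95, 0.99)) -> np.ndarray:
    """Label each cell with the highest confidence level its slope passes.

    Two-sided t-test on the slope; returned matrix holds the highest passed
    level (e.g. 0.99), 0.0 for not significant, NaN where undefined.
    """
    if len(levels) == 0:
        raise ValueError("levels must be non-empty")
    levels = sorted(levels)
    if not all(0 < lv < 1 for lv in levels):
        raise ValueError("confidence levels must be in (0, 1)")
    mask = np.zeros_like(result.pvalue)
    for lv in levels:
        mask = np.where(result.pvalue < 1.0 - lv, lv, mask)
    return np.where(np.isnan(result.pvalue), np.nan, mask)


def _in_any(wl: float, windows) -> bool:
    return any(lo <= wl <= hi for lo, hi in windows)


def best_ratio(
    result: OBRAResult, region_constraint: Sequence[tuple[float, float]] | None = None
) -> tuple[float, float, float]:
    """Return (lambda1, lambda2, r2) of the strongest band pair.

    Searches the lower triangle; an optional list of wavelength windows
    restricts candidates so that every window contains at least one of the
    two bands (e.g. require one band in 825-925 nm).  Exact r2 ties are
    broken by larger |slope|, then by smaller wavelengths.  The pair is
    oriented so the fitted slope is nonnegative (X grows with depth).
    """
    wl = result.wavelengths
    best = None  # (r2, abs_slope, lam1, lam2, slope_ij)
    for i in range(result.n_bands):
        for j in range(i):
            r2 = result.r2[i, j]
            if np.isnan(r2):
                continue
            if region_constraint is not None and not all(
                _in_any(wl[i], [w]) or _in_any(wl[j], [w]) for w in region_constraint
            ):
                continue
            cand = (r2, abs(result.slope[i, j]), -wl[j], -wl[i])
            if best is None or cand > best[0]:
                best = (cand, i, j)
    if best is None:
        raise ValueError("no valid OBRA cell (all missing or excluded)")
    _, i, j = best
    # orient numerator/denominator so slope >= 0
    if result.slope[i, j] >= 0:
        lam1, lam2 = wl[i], wl[j]
    else:
        lam1, lam2 = wl[j], wl[i]
    return float(lam1), float(lam2), float(result.r2[i, j])


def export_matrix(result: OBRAResult, out_dir) -> None:
    """Write r2/slope/intercept/pvalue matrices as CSVs with wavelength headers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    idx = pd.Index(result.wavelengths, name="wavelength_nm")
    for name in ("r2", "slope", "intercept", "pvalue", "n_obs"):
        pd.DataFrame(getattr(result, name), index=idx, columns=idx).to_csv(
            out / f"obra_{name}.csv"
        )


def read_matrix(out_dir) -> OBRAResult:
    out = Path(out_dir)
    mats = {}
    wl = None
    for name in ("r2", "slope", "intercept", "pvalue", "n_obs"):
        df = pd.read_csv(out / f"obra_{name}.csv", index_col=0)
        m = df.to_numpy(dtype=float)
        if m.shape[0] != m.shape[1]:
            raise ValueError(f"obra_{name}.csv is not square")
        this_wl = df.index.to_numpy(dtype=float)
        if wl is None:
            wl = this_wl
        elif not np.allclose(wl, this_wl):
            raise ValueError("wavelength headers differ between matrix files")
        mats[name] = m
    return OBRAResult(wavelengths=wl, **mats)


def plot_obra_matrix(result: OBRAResult, path=None, levels=(0.95, 0.99)):
    """Render the matrix: lower triangle R², upper triangle significance shading."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = result.n_bands
    img = np.full((n, n), np.nan)
    tri = np.tril_indices(n, -1)
    img[tri] = result.r2[tri]
    sig = significance_mask(result, levels)
    triu = np.triu_indices(n, 1)
    img_sig = np.full((n, n), np.nan)
    img_sig[triu] = sig[triu]
    fig, ax = plt.subplots(figsize=(6, 5))
    ext = [result.wavelengths[0], result.wavelengths[-1]] * 2
    ax.imshow(img_sig, cmap="Greys", vmin=0, vmax=1.2,
              extent=[ext[0], ext[1], ext[1], ext[0]], interpolation="nearest")
    im = ax.imshow(img, cmap="viridis", vmin=0, vmax=1,
                   extent=[ext[0], ext[1], ext[1], ext[0]], interpolation="nearest")
    fig.colorbar(im, ax=ax, label="R²")
    ax.set_xlabel("denominator wavelength (nm)")
    ax.set_ylabel("numerator wavelength (nm)")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
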