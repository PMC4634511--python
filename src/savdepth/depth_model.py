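"""Log-linear depth models from polygon DN statistics.

The polygon DN statistics stand in for total at-sensor radiance.  For a
single band the log-transformed statistic, and for a band ratio the log
ratio X, are regressed on measured submergence depth:

    ln(predictor) = a + b * d

and inverted algebraically for mapping:

    d_e = (ln(predictor) - a) / b

The per-polygon maximum DN is the default statistic: vegetation canopies
are heterogeneous (gaps, shading), so means under-represent top-of-canopy
reflectance while the maximum tracks it.  Validation regresses predicted
on measured depth (hold-out or cross-site) and reports the mean absolute
depth error alongside the regression diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from skimage.draw import disk

from .preprocess import flag_glint
from .raster import MultiBandComposite

__all__ = [
    "DepthSampleSet",
    "PredictorSpec",
    "DepthModel",
    "ValidationReport",
    "STATISTICS",
    "extract_polygon_stats",
    "predictor_value",
    "fit_depth_model",
    "model_matrix",
    "invert_depth",
    "holdout_split",
    "validate",
]

STATISTICS = ("max", "min", "mean", "sd")


@dataclass
class DepthSampleSet:
    """Per-polygon DN statistics with measured depths.

    ``data`` columns: ``id, x, y, diameter_m, depth_cm`` plus, for every
    band, ``<band>_max/_min/_mean/_sd/_count/_excluded``.
    """

    data: pd.DataFrame
    band_names: list[str]

    def __post_init__(self) -> None:
        required = ["id", "x", "y", "diameter_m", "depth_cm"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"sample table missing columns {missing}")
        if (self.data["depth_cm"] < 0).any():
            raise ValueError("measured depths must be >= 0 cm")
        for b in self.band_names:
            cnt = self.data[f"{b}_count"]
            if (cnt <= 0).any():
                raise ValueError(f"zero valid pixels for band {b} in some polygon")
            # tolerance: the mean of many identical values can drift by an ulp
            tol = 1e-9 * self.data[f"{b}_max"].abs() + 1e-12
            bad = (self.data[f"{b}_min"] > self.data[f"{b}_mean"] + tol) | (
                self.data[f"{b}_mean"] > self.data[f"{b}_max"] + tol
            )
            if bad.any():
                raise ValueError(f"inconsistent DN statistics for band {b}")

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, index) -> "DepthSampleSet":
        return DepthSampleSet(self.data.loc[index].reset_index(drop=True), self.band_names)

    def to_csv(self, path) -> None:
        self.data.to_csv(Path(path), index=False)

    @classmethod
    def from_csv(cls, path) -> "DepthSampleSet":
        df = pd.read_csv(Path(path))
        bands = sorted({c[: -len("_max")] for c in df.columns if c.endswith("_max")})
        return cls(df, bands)


@dataclass(frozen=True)
class PredictorSpec:
    """Which predictor to regress on depth: a band or a band ratio."""

    kind: str  # "single" | "ratio"
    band1: str
    band2: str | None = None
    statistic: str = "max"

    def __post_init__(self) -> None:
        if self.kind not in ("single", "ratio"):
            raise ValueError("kind must be 'single' or 'ratio'")
        if self.kind == "ratio":
            if not self.band2 or self.band2 == self.band1:
                raise ValueError("ratio requires two distinct bands")
        if self.statistic not in STATISTICS:
            raise ValueError(f"statistic must be one of {STATISTICS}")

    @property
    def name(self) -> str:
        if self.kind == "single":
            return f"{self.band1}({self.statistic})"
        return f"{self.band1}/{self.band2}({self.statistic})"


@dataclass
class DepthModel:
    """Fitted ln-predictor = a + b*d line with inversion d = (p - a)/b."""

    spec: PredictorSpec
    intercept: float  # a
    slope: float  # b
    r2: float
    n: int
    pvalue: float
    stderr: float = float("nan")
    site: str = ""

    def to_json(self, path) -> None:
        payload = {
            "spec": {
                "kind": self.spec.kind,
                "band1": self.spec.band1,
                "band2": self.spec.band2,
                "statistic": self.spec.statistic,
            },
            "intercept": self.intercept,
            "slope": self.slope,
            "r2": self.r2,
            "n": self.n,
            "pvalue": self.pvalue,
            "stderr": self.stderr,
            "site": self.site,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "DepthModel":
        d = json.loads(Path(path).read_text())
        return cls(spec=PredictorSpec(**d.pop("spec")), **d)


@dataclass
class ValidationReport:
    """Agreement of predicted vs measured depth.

    ``se_slope`` is the standard error of the regression slope,
    ``se_estimate`` the residual standard error of the predicted-vs-
    measured regression (both are reported since either reading of
    "standard error" is in use).  ``mae_cm`` is the mean absolute depth
    error; ``error_slope_p`` the significance of a depth-vs-error trend.
    """

    r2: float
    slope: float
    intercept: float
    se_slope: float
    se_estimate: float
    mae_cm: float
    n: int
    residuals: np.ndarray = field(repr=False, default=None)
    error_slope_p: float = float("nan")


def extract_polygon_stats(
    composite: MultiBandComposite,
    polygons: pd.DataFrame,
    glint_percentile: float | None = None,
) -> DepthSampleSet:
    """Compute per-polygon, per-band DN statistics over valid pixels.

    Polygons are circles (center x/y in metres, diameter in metres).
    Saturated pixels are excluded by the glint rule (always); an optional
    upper-percentile exclusion can be added.  Exclusion counts are kept.
    """
    gt = composite.transform
    sat = composite.saturation_level
    rows = []
    for _, poly in polygons.iterrows():
        prow, pcol = gt.world_to_pixel(poly["x"], poly["y"])
        radius_px = 0.5 * float(poly["diameter_m"]) / gt.pixel_size
        rr, cc = disk((float(prow), float(pcol)), radius_px, shape=composite.shape)
        if rr.size == 0:
            raise ValueError(f"polygon {poly['id']} falls outside the raster")
        rec = {
            "id": poly["id"],
            "x": poly["x"],
            "y": poly["y"],
            "diameter_m": poly["diameter_m"],
            "depth_cm": poly["depth_cm"],
        }
        for b in composite.bands:
            vals = b.dn[rr, cc]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise ValueError(
                    f"polygon {poly['id']} has no valid pixels in band {b.band.name}"
                )
            keep = flag_glint(vals, saturation_level=sat, percentile=glint_percentile)
            kept = vals[keep]
            if kept.size == 0:
                raise ValueError(
                    f"polygon {poly['id']} fully glint-flagged in band {b.band.name}"
                )
            name = b.band.name
            rec[f"{name}_max"] = float(kept.max())
            rec[f"{name}_min"] = float(kept.min())
            rec[f"{name}_mean"] = float(kept.mean())
            rec[f"{name}_sd"] = float(kept.std())
            rec[f"{name}_count"] = int(kept.size)
            rec[f"{name}_excluded"] = int(vals.size - kept.size)
        rows.append(rec)
    return DepthSampleSet(pd.DataFrame(rows), composite.band_names)


def predictor_value(sample, spec: PredictorSpec) -> float:
    """ln of the chosen statistic (single band) or statistic ratio (ratio)."""
    v1 = float(sample[f"{spec.band1}_{spec.statistic}"])
    if spec.kind == "single":
        if v1 <= 0:
            raise ValueError(f"nonpositive statistic {spec.band1}_{spec.statistic}={v1}")
        return float(np.log(v1))
    v2 = float(sample[f"{spec.band2}_{spec.statistic}"])
    if v1 <= 0 or v2 <= 0:
        raise ValueError("nonpositive statistic in ratio predictor")
    return float(np.log(v1 / v2))


def _predictors(samples: DepthSampleSet, spec: PredictorSpec) -> np.ndarray:
    return np.array([predictor_value(row, spec) for _, row in samples.data.iterrows()])


def fit_depth_model(samples: DepthSampleSet, spec: PredictorSpec, site: str = "") -> DepthModel:
    """OLS fit of the ln-predictor on measured depth (predictor = a + b*d)."""
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to fit a depth model")
    d = samples.data["depth_cm"].to_numpy(dtype=float)
    if np.var(d) == 0:
        raise ValueError("zero depth variance: cannot fit a depth model")
    p = _predictors(samples, spec)
    res = stats.linregress(d, p)
    if res.slope == 0:
        raise ValueError("fitted slope is zero; model not invertible")
    return DepthModel(
        spec=spec,
        intercept=float(res.intercept),
        slope=float(res.slope),
        r2=float(res.rvalue**2),
        n=len(samples),
        pvalue=float(res.pvalue),
        stderr=float(res.stderr),
        site=site,
    )


def model_matrix(
    samples: DepthSampleSet, bands: list[str] | None = None, statistic: str = "max"
) -> pd.DataFrame:
    """R² grid over bands: diagonal = single-band fits, lower triangle =
    ratio fits (row band / column band).  Degenerate cells are NaN."""
    bands = bands or samples.band_names
    n = len(bands)
    out = np.full((n, n), np.nan)
    for i, bi in enumerate(bands):
        for j in range(i + 1):
            if i == j:
                spec = PredictorSpec("single", bi, statistic=statistic)
            else:
                spec = PredictorSpec("ratio", bi, bands[j], statistic=statistic)
            try:
                model = fit_depth_model(samples, spec)
            except ValueError:
                continue
            out[i, j] = model.r2
            if i != j:
                out[j, i] = model.r2
    return pd.DataFrame(out, index=bands, columns=bands)


def invert_depth(model: DepthModel, predictor: float | np.ndarray):
    """Algebraic inversion d_e = (predictor - a) / b."""
    if model.slope == 0:
        raise ValueError("model slope is zero; cannot invert")
    return (np.asarray(predictor, dtype=float) - model.intercept) / model.slope


def holdout_split(
    samples: DepthSampleSet, fraction: float = 0.15, seed: int = 0
) -> tuple[DepthSampleSet, DepthSampleSet]:
    """Random disjoint train/test split; |test| = round(fraction * n)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(samples)
    n_test = int(round(fraction * n))
    if n - n_test < 3:
        raise ValueError("too few samples to leave a trainable split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return samples.subset(train_idx), samples.subset(test_idx)


def validate(model: DepthModel, samples: DepthSampleSet) -> ValidationReport:
    """Predict depths for a sample set and compare with measurements.

    Regresses predicted on measured depth; reports R², slope, intercept,
    both standard errors, the mean absolute depth error and a test for a
    depth-dependent error trend.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to validate")
    measured = samples.data["depth_cm"].to_numpy(dtype=float)
    predicted = invert_depth(model, _predictors(samples, model.spec))
    if np.var(measured) == 0:
        raise ValueError("zero variance in measured depths")
    res = stats.linregress(measured, predicted)
    residuals = predicted - measured
    fitted = res.intercept + res.slope * measured
    dof = max(len(samples) - 2, 1)
    se_est = float(np.sqrt(np.sum((predicted - fitted) ** 2) / dof))
    err_res = stats.linregress(measured, residuals)
    return ValidationReport(
        r2=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        se_slope=float(res.stderr),
        se_estimate=se_est,
        mae_cm=float(np.mean(np.abs(residuals))),
        n=len(samples),
        residuals=residuals,
        error_slope_p=float(err_res.pvalue),
    )
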