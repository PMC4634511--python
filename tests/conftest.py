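import numpy as np
import pandas as pd
import pytest

import savdepth as sd


def ols_oracle(x, y):
    """Independent normal-equations OLS oracle: returns (slope, intercept, r2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    return float(beta[1]), float(beta[0]), float(r2)


@pytest.fixture(scope="session")
def grid6():
    return np.array([450.0, 550.0, 650.0, 750.0, 850.0, 950.0])


@pytest.fixture(scope="session")
def water_k6(grid6):
    return sd.make_attenuation_curve(grid6, "water_like")


@pytest.fixture(scope="session")
def noiseless_library(grid6, water_k6):
    """Exactly log-linear library: single archetype, no noise, r_c = 0."""
    cfg = sd.SceneConfig(noise_sd=0.0, seed=1)
    lib, depths = sd.simulate_spectral_survey(
        12, (5.0, 50.0), ("vegetation",), k=water_k6, config=cfg, grid=grid6
    )
    return lib, depths


def make_step_scene(seed=0, n_steps=8, depth_lo=5.0, depth_hi=40.0, **cfg_kwargs):
    """Scene whose depth is constant within wide row bands, with polygons
    centered in each band: polygon statistics then correspond exactly to the
    annotated depth (no within-polygon depth spread)."""
    defaults = dict(
        noise_sd=0.0, glint_fraction=0.0, quantize=False, seed=seed,
        pixel_size_m=0.0048, n_polygons=4,
    )
    defaults.update(cfg_kwargs)
    config = sd.SceneConfig(**defaults)
    shape = (n_steps * 64, 256)
    step_depths = np.linspace(depth_lo, depth_hi, n_steps)
    depth = np.repeat(step_depths, 64)[:, None] * np.ones((1, shape[1]))
    comp, truth, _ = sd.simulate_scene(config, shape=shape, depth=depth)
    gt = comp.transform
    rows = np.arange(n_steps) * 64 + 32
    cols = np.full(n_steps, shape[1] // 2)
    xs, ys = gt.pixel_to_world(rows, cols)
    polys = pd.DataFrame(
        {
            "id": [f"p{i:02d}" for i in range(n_steps)],
            "x": xs,
            "y": ys,
            "diameter_m": config.polygon_diameter_m,
            "depth_cm": step_depths,
        }
    )
    return comp, truth, polys


@pytest.fixture(scope="session")
def step_scene():
    return make_step_scene()
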