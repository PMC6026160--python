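"""Shared fixtures: compact simulated scenes for fast tests."""

from __future__ import annotations

import numpy as np
import pytest

from duohct.config import (
    HeterogeneityConfig,
    PhantomConfig,
    RegionSpec,
    RunConfig,
    default_config,
)


def small_config(seed: int = 0, noise: bool = False, bhct: float = 0.401,
                 heterogeneity: bool = True, vessels: bool = True) -> RunConfig:
    """A 100x140 scene with the same anatomy as the default control brain,
    scaled down so per-test simulation stays in the millisecond range."""
    regions = [
        RegionSpec(name="cortex", label=1, shape="ellipse_shell",
                   center_rc=(50.0, 45.0), axes_rc=(36.0, 33.0),
                   inner_axes_rc=(26.0, 24.0), vv_pct=3.5, thct_frac=0.296),
        RegionSpec(name="white_matter", label=2, shape="ellipse_shell",
                   center_rc=(50.0, 45.0), axes_rc=(26.0, 24.0),
                   inner_axes_rc=(18.0, 17.0), vv_pct=2.0, thct_frac=0.280),
        RegionSpec(name="striatum", label=3, shape="ellipse",
                   center_rc=(50.0, 45.0), axes_rc=(18.0, 17.0),
                   vv_pct=3.0, thct_frac=0.288),
    ]
    if vessels:
        regions += [
            RegionSpec(name="vessel_1", label=21, shape="disk",
                       center_rc=(30.0, 45.0), radius_px=1.8, vv_pct=30.0,
                       thct_frac=None, overlay=True),
            RegionSpec(name="vessel_2", label=22, shape="disk",
                       center_rc=(55.0, 38.0), radius_px=1.5, vv_pct=30.0,
                       thct_frac=None, overlay=True),
        ]
    cfg = RunConfig(seed=seed)
    cfg.phantom = PhantomConfig(
        shape_rc=(100, 140), regions=regions,
        heterogeneity=HeterogeneityConfig() if heterogeneity
        else HeterogeneityConfig(vv_rel_sd=0.0, thct_abs_sd=0.0),
    )
    cfg.layout.pure_i_spot.center_rc = (22.0, 115.0)
    cfg.layout.pure_i_spot.radius_px = 8.0
    cfg.layout.blood_spot.center_rc = (75.0, 115.0)
    cfg.layout.blood_spot.radius_px = 9.0
    cfg.panel.bhct_capillary = bhct
    cfg.noise.enabled = noise
    return cfg


@pytest.fixture
def noiseless_scene():
    from duohct.pipeline import simulate_scene

    return simulate_scene(small_config(seed=7, noise=False))


@pytest.fixture
def noisy_scene():
    from duohct.pipeline import simulate_scene

    return simulate_scene(small_config(seed=7, noise=True))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def control_config():
    return default_config(seed=3)
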