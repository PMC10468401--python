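"""Shared fixtures: small synthetic scenes and localization tables."""

import warnings

import numpy as np
import pandas as pd
import pytest

from piezoblade.synthetic_data import (
    EmissionParams,
    GeometryParams,
    emit_localizations,
    generate_scene,
)

# sklearn's EM occasionally reports non-convergence on degenerate fixtures;
# the pipeline handles those cases explicitly.
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noiseless_emission():
    return EmissionParams(
        sigma_loc=0.0,
        traces_per_fluor_mean=4.0,
        locs_per_trace_mean=10.0,
        background_trace_density=0.0,
        streak_density=0.0,
    )


@pytest.fixture
def clean_emission():
    """6 nm noise, no background or streaks."""
    return EmissionParams(
        sigma_loc=6.0,
        traces_per_fluor_mean=6.0,
        locs_per_trace_mean=20.0,
        background_trace_density=0.0,
        streak_density=0.0,
    )


@pytest.fixture
def rigid_geometry():
    """Zero conformational spread: identical equilateral molecules."""
    return GeometryParams(mu_radius=25.0 / np.sqrt(3), sigma_radius=0.0, sigma_theta=0.0, sigma_z=0.0)


@pytest.fixture
def small_scene(rigid_geometry):
    return generate_scene(
        rigid_geometry, 5, field_extent=(2000.0, 2000.0), min_separation=300.0, p_label=1.0, seed=7
    )


@pytest.fixture
def small_table(small_scene, clean_emission):
    return emit_localizations(small_scene, clean_emission, seed=8)


def gaussian_blob(rng, centre, sigma, n, trace_prefix="t", truth="m0000"):
    """Localization rows for one isotropic cloud, split into traces of 10."""
    pts = np.asarray(centre, dtype=float) + sigma * rng.standard_normal((n, 3))
    rows = {
        "trace_id": [f"{trace_prefix}{i // 10:04d}" for i in range(n)],
        "x_nm": pts[:, 0],
        "y_nm": pts[:, 1],
        "z_nm": pts[:, 2],
        "truth_id": [truth] * n,
    }
    return pd.DataFrame(rows)
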