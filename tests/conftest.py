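"""Shared phantom fixtures.

Unit tests run on small phantoms (coarse 2 µm voxels, ~0.7 Mvoxel grids) so
the whole suite stays fast; the acceptance tests build full-size phantoms at
the nano-CT sampling themselves.
"""

import numpy as np
import pytest

import cortiquant as cq


SMALL_VOXEL = 2.0


def small_spec(**overrides) -> cq.PhantomSpec:
    base = dict(
        grid_shape=(48, 120, 120),
        voxel_size_um=SMALL_VOXEL,
        outer_radii_um=(105.0, 90.0),
        inner_radii_um=(65.0, 55.0),
        canal_specs=(
            cq.CanalSpec(theta_deg=0.0, z_frac=0.5, diameter_um=24.0),
            cq.CanalSpec(theta_deg=120.0, z_frac=0.3, diameter_um=20.0,
                         inclination_deg=10.0),
            cq.CanalSpec(theta_deg=-100.0, z_frac=0.7, diameter_um=28.0),
        ),
        # lacunae above the 2 µm sampling limit of these coarse fixtures
        lacuna_semiaxes_um=(8.0, 5.0, 5.0),
        lacuna_count=8,
        seed=7,
    )
    base.update(overrides)
    return cq.PhantomSpec(**base)


@pytest.fixture(scope="session")
def phantom_three_canals():
    spec = small_spec()
    volume, truth = cq.generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def quantified_three_canals(phantom_three_canals):
    _, volume, truth = phantom_three_canals
    return truth, cq.quantify_volume(volume)


@pytest.fixture(scope="session")
def solid_shell():
    """Intact elliptic shell, no voids, no blur: bone mask is exact."""
    spec = small_spec(canal_specs=(), lacuna_count=0, blur_sigma_um=0.0)
    volume, truth = cq.generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def single_canal_phantom():
    """One canal at theta=90, mid-height, for panorama localization."""
    spec = small_spec(
        canal_specs=(cq.CanalSpec(theta_deg=90.0, z_frac=0.5, diameter_um=24.0),),
        lacuna_count=0,
    )
    volume, truth = cq.generate_phantom(spec)
    result = cq.quantify_volume(volume)
    return spec, truth, result
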