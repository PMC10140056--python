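"""Shared fixtures: synthetic eyes at several scales.

``cfg_iso`` / ``ref_iso`` cover a 6.5 mm isotropic raster that contains
the full ETDRS grid (used for regional statistics and inversion tests);
``cfg_default`` is the anisotropic 61×512 macular protocol;
``cfg_vol`` is a small volume for B-scan editing tests.
"""

import warnings

import numpy as np
import pytest

from rodcone import (
    EtdrsGrid,
    GridGeometry,
    ProportionMap,
    ReferenceModel,
    SurvivalModel,
    SynthConfig,
    synth_healthy_volume,
    synth_reference,
)
from rodcone.etdrs import region_masks
from rodcone.maps import ThicknessMap


@pytest.fixture(scope="session")
def cfg_iso() -> SynthConfig:
    return SynthConfig(
        n_rows=65, n_cols=65, dx_mm=0.1, dy_mm=0.1,
        fovea_rc=(32.0, 32.0), nerve_rc=(30.0, 78.0),
    )


@pytest.fixture(scope="session")
def ref_iso(cfg_iso) -> ReferenceModel:
    return synth_reference(cfg_iso)


@pytest.fixture(scope="session")
def model_iso(ref_iso) -> SurvivalModel:
    return SurvivalModel(ref_iso)


@pytest.fixture(scope="session")
def cfg_default() -> SynthConfig:
    return SynthConfig()


@pytest.fixture(scope="session")
def ref_default(cfg_default) -> ReferenceModel:
    return synth_reference(cfg_default)


@pytest.fixture(scope="session")
def cfg_vol() -> SynthConfig:
    return SynthConfig(
        n_rows=13, n_cols=64, dx_mm=0.1, dy_mm=0.1,
        fovea_rc=(6.0, 32.0), nerve_rc=(5.0, 78.0), n_depth=496,
    )


@pytest.fixture(scope="session")
def vol_and_map(cfg_vol):
    return synth_healthy_volume(cfg_vol)


@pytest.fixture(scope="session")
def ref_vol(cfg_vol, vol_and_map) -> ReferenceModel:
    """Reference whose normal thickness is the volume's own segmented ONL,
    so voxel targets and map thicknesses agree exactly."""
    vol, _ = vol_and_map
    field_ref = synth_reference(cfg_vol)
    return ReferenceModel(
        geometry=cfg_vol.geometry,
        normal_thickness=vol.thickness_map_um("ONL"),
        p_rods=field_ref.p_rods,
    )


def make_reference(geometry: GridGeometry, thickness: np.ndarray, p_rods: np.ndarray) -> ReferenceModel:
    """Hand-built reference with explicit composition (for engineered cases)."""
    missing = np.isnan(np.asarray(p_rods, float))
    return ReferenceModel(
        geometry=geometry,
        normal_thickness=np.asarray(thickness, float),
        p_rods=ProportionMap(geometry, np.where(missing, 0.0, p_rods), missing),
    )


@pytest.fixture(scope="session")
def iso_masks(cfg_iso):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return region_masks(EtdrsGrid(), cfg_iso.geometry)


@pytest.fixture
def uniform_map(cfg_iso) -> ThicknessMap:
    return ThicknessMap(cfg_iso.geometry, np.full((65, 65), 80.0), kind="normal")
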