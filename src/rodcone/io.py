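"""File formats: TIFF+JSON thickness maps, HDF5 reference models and
volumes, CSV density / measurement / estimate tables."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .bscan import SegmentedVolume
from .errors import InvalidArgumentError
from .geometry import GridGeometry
from .maps import ThicknessMap
from .reference import DensitySample, ProportionMap, ReferenceModel

SPHERICAL_COLUMNS = ["longitude_deg", "colatitude_deg", "rods_per_mm2", "cones_per_mm2"]
PLANAR_COLUMNS = ["x_mm", "y_mm", "rods_per_mm2", "cones_per_mm2"]


# -- density sample CSV ---------------------------------------------------
def write_density_csv(samples: list[DensitySample], path) -> None:
    pd.DataFrame(
        {
            "longitude_deg": [s.longitude_deg for s in samples],
            "colatitude_deg": [s.colatitude_deg for s in samples],
            "rods_per_mm2": [s.rods for s in samples],
            "cones_per_mm2": [s.cones for s in samples],
        }
    ).to_csv(path, index=False)


def read_density_csv(path, retinal_radius_mm: float | None = None) -> list[DensitySample]:
    """Read density samples; accepts the spherical dialect (longitude_deg,
    colatitude_deg, …) or the planar one (x_mm, y_mm, …).  Planar rows are
    converted back to spherical coordinates through the azimuthal-
    equidistant projection (radius required)."""
    df = pd.read_csv(path)
    if set(SPHERICAL_COLUMNS).issubset(df.columns):
        return [
            DensitySample(r.longitude_deg, r.colatitude_deg, r.rods_per_mm2, r.cones_per_mm2)
            for r in df.itertuples(index=False)
        ]
    if set(PLANAR_COLUMNS).issubset(df.columns):
        from .geometry import DEFAULT_RETINAL_RADIUS_MM

        R = retinal_radius_mm if retinal_radius_mm is not None else DEFAULT_RETINAL_RADIUS_MM
        ecc = np.hypot(df["x_mm"], df["y_mm"])
        lon = np.degrees(np.arctan2(df["y_mm"], df["x_mm"]))
        colat = np.degrees(ecc / R)
        return [
            DensitySample(float(lo), float(co), float(r), float(c))
            for lo, co, r, c in zip(lon, colat, df["rods_per_mm2"], df["cones_per_mm2"])
        ]
    raise InvalidArgumentError(
        f"density CSV must contain columns {SPHERICAL_COLUMNS} or {PLANAR_COLUMNS}"
    )


# -- thickness map TIFF + JSON sidecar ------------------------------------
def _sidecar(path) -> Path:
    return Path(path).with_suffix(".json")


def write_thickness_tiff(tmap: ThicknessMap, path) -> None:
    tifffile.imwrite(path, tmap.values.astype(np.float32))
    meta = tmap.geometry.to_dict()
    meta.update({"units": "um", "kind": tmap.kind, **tmap.metadata})
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_thickness_tiff(path) -> ThicknessMap:
    values = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(_sidecar(path).read_text())
    for key in ("n_rows", "n_cols", "dx_mm", "dy_mm", "fovea_rc", "nerve_rc", "laterality"):
        if key not in meta:
            raise InvalidArgumentError(f"thickness metadata is missing field {key!r}")
    geometry = GridGeometry.from_dict(meta)
    extra = {k: v for k, v in meta.items() if k not in geometry.to_dict() and k not in ("units", "kind")}
    return ThicknessMap(geometry, values, kind=meta.get("kind", "observed"), metadata=extra)


# -- reference model HDF5 --------------------------------------------------
def write_reference_h5(ref: ReferenceModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("normal_thickness", data=ref.normal_thickness)
        f.create_dataset("p_rods", data=ref.p_rods.p_rods)
        f.create_dataset("missing_mask", data=ref.missing_mask)
        g = f.create_group("metadata")
        for k, v in ref.geometry.to_dict().items():
            g.attrs[k] = v


def read_reference_h5(path) -> ReferenceModel:
    with h5py.File(path, "r") as f:
        geometry = GridGeometry.from_dict(
            {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in f["metadata"].attrs.items()}
        )
        ref = ReferenceModel(
            geometry=geometry,
            normal_thickness=f["normal_thickness"][()],
            p_rods=ProportionMap(geometry, f["p_rods"][()], f["missing_mask"][()].astype(bool)),
        )
    return ref


# -- segmented volume HDF5 -------------------------------------------------
def write_volume_h5(vol: SegmentedVolume, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("voxels", data=vol.voxels)
        f.create_dataset("surfaces", data=vol.surfaces)
        f.attrs["dz_um"] = vol.dz_um
        f.attrs["layer_names"] = list(vol.layer_names)
        g = f.create_group("metadata")
        for k, v in vol.geometry.to_dict().items():
            g.attrs[k] = v
        for k, v in vol.metadata.items():
            if isinstance(v, (str, int, float, bool, np.number)):
                g.attrs[f"meta_{k}"] = v


def read_volume_h5(path) -> SegmentedVolume:
    with h5py.File(path, "r") as f:
        geo_keys = ("n_rows", "n_cols", "dx_mm", "dy_mm", "fovea_rc", "nerve_rc", "laterality")
        attrs = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in f["metadata"].attrs.items()}
        geometry = GridGeometry.from_dict({k: attrs[k] for k in geo_keys})
        meta = {k[5:]: v for k, v in attrs.items() if k.startswith("meta_")}
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in f.attrs["layer_names"]]
        return SegmentedVolume(
            voxels=f["voxels"][()],
            surfaces=f["surfaces"][()],
            dz_um=float(f.attrs["dz_um"]),
            geometry=geometry,
            layer_names=tuple(names),
            metadata=meta,
        )


# -- B-scan image export ---------------------------------------------------
def export_bscan_png(vol: SegmentedVolume, b_index: int, path) -> None:
    """One B-scan as an 8-bit grayscale image for visual inspection."""
    from PIL import Image

    sl = np.asarray(vol.voxels[b_index], dtype=float)
    lo, hi = np.percentile(sl, [1, 99])
    img = np.clip((sl - lo) / max(hi - lo, 1e-9), 0, 1)
    Image.fromarray((img * 255).astype(np.uint8)).save(path)
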