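"""Readers and writers for the plain-text/image exchange formats.

Contours travel as JSON (per frame: the shared angle grid in degrees and
endo/epi radii in mm), sector profiles and section tables as CSV, section
partitions as JSON lists of ``{label, start_deg, end_deg}``, intensity
grids as float32 TIFF (PNG for 8-bit previews), and run configs as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import IntensityImage, SectionPartition, SectorProfile, SliceGeometry


def save_geometry_json(geom: SliceGeometry, path):
    payload = {
        "center_xy_mm": list(geom.center_xy_mm),
        "theta_deg": geom.theta_deg.tolist(),
        "endo_mm": geom.endo_mm.tolist(),
        "epi_mm": geom.epi_mm.tolist(),
        "ed_frame_index": geom.ed_frame_index,
        "es_frame_index": geom.es_frame_index,
    }
    Path(path).write_text(json.dumps(payload))


def load_geometry_json(path) -> SliceGeometry:
    d = json.loads(Path(path).read_text())
    return SliceGeometry(
        center_xy_mm=tuple(d["center_xy_mm"]),
        theta_deg=np.asarray(d["theta_deg"]),
        endo_mm=np.asarray(d["endo_mm"]),
        epi_mm=np.asarray(d["epi_mm"]),
        ed_frame_index=d.get("ed_frame_index", 0),
        es_frame_index=d.get("es_frame_index"),
    )


def save_profile_csv(profile: SectorProfile, path):
    pd.DataFrame(
        {"sector_index": np.arange(profile.K), "value": profile.values}
    ).to_csv(path, index=False)


def load_profile_csv(path, quantity: str = "", units: str = "") -> SectorProfile:
    df = pd.read_csv(path)
    return SectorProfile(df["value"].to_numpy(), quantity=quantity, units=units)


def save_partition_json(partition: SectionPartition, path):
    payload = {
        "landmark_angle_deg": partition.landmark_angle_deg,
        "sections": [
            {"label": lab, "start_deg": s, "end_deg": e}
            for lab, s, e in partition.sections
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_partition_json(path) -> SectionPartition:
    d = json.loads(Path(path).read_text())
    return SectionPartition(
        [(s["label"], s["start_deg"], s["end_deg"]) for s in d["sections"]],
        landmark_angle_deg=d.get("landmark_angle_deg", 0.0),
    )


def save_intensity_tiff(img: IntensityImage, path):
    tifffile.imwrite(
        path,
        img.pixels.astype(np.float32),
        metadata={"pixel_spacing_mm": img.pixel_spacing_mm},
    )


def load_intensity(path, mask_path, pixel_spacing_mm: float) -> IntensityImage:
    """Load a TIFF/PNG intensity grid with a PNG (nonzero = myocardium) mask."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path).astype(float)
    else:
        pixels = np.asarray(iio.imread(path), dtype=float)
        if pixels.ndim == 3:
            pixels = pixels[..., 0]
    mask = np.asarray(iio.imread(mask_path)) > 0
    if mask.ndim == 3:
        mask = mask[..., 0]
    return IntensityImage(pixels, pixel_spacing_mm, mask)


def save_mask_png(mask: np.ndarray, path):
    iio.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))


def load_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_yaml(obj, path):
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))
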