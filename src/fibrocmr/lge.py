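"""LGE scar delineation and per-sector transmurality / signal exports.

Scar is delineated on the late-gadolinium-enhancement image by the two
threshold families used clinically:

* FWHM — threshold at half the maximal signal intensity within a scar seed
  region (default: the whole myocardium); pixels at or above the threshold
  are scar.
* n-SD-from-remote — threshold at mean + n standard deviations of a remote
  (healthy) myocardial region; pixels strictly above the threshold are
  scar.  The SD is the population SD (divisor N).

Manual correction removes an exclusion region from a delineated mask (the
method tag gains an ``m`` suffix).  The fraction of transmurality (%TM) is
area based: per angular wedge, scar pixel count over myocardial pixel
count.  Myocardial signal intensity (MSI) is the per-wedge mean LGE
intensity in arbitrary units.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .core import (
    IntensityImage,
    SectorProfile,
    SliceGeometry,
    circular_distance_deg,
    sector_index,
    wrap_deg,
)


@dataclass
class ScarMask:
    """Per-pixel scar labeling plus the delineation method that produced it."""

    scar: np.ndarray
    myocardium: np.ndarray
    method_tag: str
    threshold_used: float
    pixel_spacing_mm: float

    def __post_init__(self):
        self.scar = np.asarray(self.scar, dtype=bool)
        self.myocardium = np.asarray(self.myocardium, dtype=bool)
        if self.scar.shape != self.myocardium.shape:
            raise ValueError("scar and myocardium grids must share a shape")
        if np.any(self.scar & ~self.myocardium):
            raise ValueError("scar pixels must lie inside the myocardial mask")

    def replace(self, **kw) -> "ScarMask":
        return dataclasses.replace(self, **kw)


def fwhm_mask(img: IntensityImage, seed_region="auto") -> ScarMask:
    """Full-width-at-half-maximum delineation.

    The threshold is half the maximal intensity within ``seed_region``
    (``"auto"`` = the whole myocardium); myocardial pixels with intensity
    greater than or equal to the threshold are scar.
    """
    if isinstance(seed_region, str) and seed_region == "auto":
        seed = img.myocardial_mask
    else:
        seed = np.asarray(seed_region, dtype=bool)
        if seed.shape != img.pixels.shape:
            raise ValueError("seed region shape must match the image")
        if np.any(seed & ~img.myocardial_mask):
            raise ValueError("seed region must lie inside the myocardium")
    if not seed.any():
        raise ValueError("empty FWHM seed region")
    threshold = 0.5 * float(img.pixels[seed].max())
    scar = img.myocardial_mask & (img.pixels >= threshold)
    return ScarMask(scar, img.myocardial_mask, "FWHM", threshold, img.pixel_spacing_mm)


def sd_remote_mask(img: IntensityImage, remote_region, n_sd: float) -> ScarMask:
    """Mean + n·SD-from-remote delineation (strict ``>`` threshold rule)."""
    remote = np.asarray(remote_region, dtype=bool)
    if remote.shape != img.pixels.shape:
        raise ValueError("remote region shape must match the image")
    if np.any(remote & ~img.myocardial_mask):
        raise ValueError("remote region must lie inside the myocardium")
    if np.count_nonzero(remote) < 2:
        raise ValueError("remote region needs at least two pixels")
    if n_sd < 0:
        raise ValueError("n_sd must be nonnegative")
    vals = img.pixels[remote]
    threshold = float(vals.mean() + n_sd * vals.std(ddof=0))
    scar = img.myocardial_mask & (img.pixels > threshold)
    tag = f"SD{n_sd:g}"
    return ScarMask(scar, img.myocardial_mask, tag, threshold, img.pixel_spacing_mm)


def apply_manual_correction(mask: ScarMask, exclusion_region) -> ScarMask:
    """Remove an exclusion region from the scar (manual-correction step)."""
    excl = np.asarray(exclusion_region, dtype=bool)
    if excl.shape != mask.scar.shape:
        raise ValueError("exclusion region shape must match the mask")
    return mask.replace(scar=mask.scar & ~excl, method_tag=mask.method_tag + "m")


def remote_region_from_span(
    img: IntensityImage,
    geom: SliceGeometry,
    center_deg: float,
    half_width_deg: float = 30.0,
) -> np.ndarray:
    """Myocardial pixels within an angular band (the lateral-wall remote)."""
    _, ang = img.polar(geom.center_xy_mm)
    return img.myocardial_mask & (
        circular_distance_deg(ang, center_deg) <= half_width_deg
    )


def _check_frames(mask_shape, spacing, geom: SliceGeometry):
    cx, cy = geom.center_xy_mm
    h, w = mask_shape
    if not (0 <= cx <= w * spacing and 0 <= cy <= h * spacing):
        raise ValueError(
            "geometry center lies outside the image extent: mask and "
            "geometry do not share a spatial frame"
        )


def transmurality_profile(
    mask: ScarMask, geom: SliceGeometry, K: int = 360
) -> SectorProfile:
    """Area-based fraction of transmurality (%) per angular sector.

    Per sector wedge: 100 × scar pixels / myocardial pixels.  Wedges
    without myocardial pixels are flagged missing (NaN).
    """
    _check_frames(mask.scar.shape, mask.pixel_spacing_mm, geom)
    _, ang = _polar_angles(mask.scar.shape, mask.pixel_spacing_mm, geom)
    idx = sector_index(ang, K)
    myo_counts = np.bincount(idx[mask.myocardium], minlength=K).astype(float)
    scar_counts = np.bincount(idx[mask.scar], minlength=K).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tm = 100.0 * scar_counts / myo_counts
    tm[myo_counts == 0] = np.nan
    return SectorProfile(tm, quantity=f"tm_{mask.method_tag}", units="%",
                         frame="native")


def msi_profile(img: IntensityImage, geom: SliceGeometry, K: int = 360) -> SectorProfile:
    """Mean myocardial LGE signal intensity per angular sector (a.u.)."""
    _check_frames(img.pixels.shape, img.pixel_spacing_mm, geom)
    _, ang = _polar_angles(img.pixels.shape, img.pixel_spacing_mm, geom)
    idx = sector_index(ang, K)
    myo = img.myocardial_mask
    counts = np.bincount(idx[myo], minlength=K).astype(float)
    sums = np.bincount(idx[myo], weights=img.pixels[myo], minlength=K)
    with np.errstate(invalid="ignore", divide="ignore"):
        msi = sums / counts
    msi[counts == 0] = np.nan
    return SectorProfile(msi, quantity="msi", units="au", frame="native")


def _polar_angles(shape, spacing, geom: SliceGeometry):
    from .core import pixel_polar_mm

    return pixel_polar_mm(shape, spacing, geom.center_xy_mm)
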