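"""Shared geometric containers and angular conventions.

Everything downstream exchanges data through three containers:

* :class:`SliceGeometry` — LV center plus per-frame endocardial/epicardial
  contours stored as polar radius functions on a fixed angular grid.
* :class:`SectorProfile` — one value per equal angular sector (K sectors of
  360/K degrees each); the universal exchange format between the CMR
  quantification stages and the registration stage.
* :class:`SectionPartition` — the histology side: ordered angular wedge
  spans, one per cut section, covering the full circle.

Angular convention (repo-wide): angles are in degrees, measured
counterclockwise in the (x, y) image coordinate basis around the LV center,
normalized to [0, 360).  After registration, 0 degrees sits at the
mid-lateral landmark.  Sector ``k`` of ``K`` covers the half-open span
``[k*360/K, (k+1)*360/K)``; values exactly on a boundary belong to the
higher sector.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

FULL_CIRCLE_DEG = 360.0
#: sector counts used for the study-style exports (strain, WT, transmurality)
PAPER_SECTOR_COUNTS = (48, 60, 360)


def wrap_deg(angle):
    """Normalize angle(s) to [0, 360)."""
    return np.mod(angle, FULL_CIRCLE_DEG)


def circular_distance_deg(a, b):
    """Smallest absolute angular distance between two angles, in [0, 180]."""
    d = np.abs(wrap_deg(a) - wrap_deg(b))
    return np.minimum(d, FULL_CIRCLE_DEG - d)


def sector_index(theta_deg, K: int):
    """Map angle(s) to sector indices 0..K-1 under the half-open convention."""
    idx = np.floor(wrap_deg(theta_deg) / (FULL_CIRCLE_DEG / K)).astype(np.intp)
    # guard against wrap_deg returning 360-eps rounding up to K
    return np.minimum(idx, K - 1)


def sector_edges_deg(K: int) -> np.ndarray:
    return np.arange(K + 1) * (FULL_CIRCLE_DEG / K)


def pixel_grid_mm(shape: tuple[int, int], pixel_spacing_mm: float):
    """(x, y) coordinates in mm of each pixel center for an (H, W) grid.

    x runs along columns, y along rows; both increase with index.  Angles
    computed from these coordinates are counterclockwise in the (x, y) basis.
    """
    h, w = shape
    y, x = np.meshgrid(
        (np.arange(h) + 0.5) * pixel_spacing_mm,
        (np.arange(w) + 0.5) * pixel_spacing_mm,
        indexing="ij",
    )
    return x, y


def pixel_polar_mm(shape, pixel_spacing_mm, center_xy_mm):
    """Per-pixel (radius_mm, angle_deg) relative to a center given in mm."""
    x, y = pixel_grid_mm(shape, pixel_spacing_mm)
    dx = x - center_xy_mm[0]
    dy = y - center_xy_mm[1]
    r = np.hypot(dx, dy)
    ang = wrap_deg(np.degrees(np.arctan2(dy, dx)))
    return r, ang


def fill_missing_sectors(values: np.ndarray) -> np.ndarray:
    """Fill NaN sectors by circular linear interpolation between neighbors.

    Wedges without any pixel (possible when the sector arc is finer than
    the pixel grid) are flagged NaN by the profile exporters; resampling
    and registration need finite values, so gaps inherit interpolated
    values from the nearest valid sectors around the circle.
    """
    values = np.asarray(values, dtype=float)
    bad = ~np.isfinite(values)
    if not bad.any():
        return values.copy()
    if bad.all():
        raise ValueError("profile has no finite sectors to interpolate from")
    k = values.size
    idx = np.arange(k)
    good = ~bad
    # unwrap circularly by tiling the valid samples one period to each side
    xp = np.concatenate([idx[good] - k, idx[good], idx[good] + k])
    fp = np.tile(values[good], 3)
    out = values.copy()
    out[bad] = np.interp(idx[bad], xp, fp)
    return out


@dataclass
class SectorProfile:
    """A quantity sampled on K equal angular sectors.

    ``values[k]`` belongs to the sector spanning ``[k*360/K, (k+1)*360/K)``
    in the frame named by ``frame``.  Missing sectors (e.g. no myocardial
    pixels in a wedge) are NaN.
    """

    values: np.ndarray
    quantity: str = ""
    units: str = ""
    frame: str = "native"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("SectorProfile requires a non-empty 1-D value array")

    @property
    def K(self) -> int:
        return self.values.size

    @property
    def sector_width_deg(self) -> float:
        return FULL_CIRCLE_DEG / self.K

    def sector_centers_deg(self) -> np.ndarray:
        return (np.arange(self.K) + 0.5) * self.sector_width_deg

    def mean(self) -> float:
        return float(np.mean(self.values))

    def replace(self, **kw) -> "SectorProfile":
        return dataclasses.replace(self, **kw)


@dataclass
class SectionPartition:
    """Ordered angular wedge spans of the histology sections.

    ``sections`` is an ordered list of ``(label, start_deg, end_deg)`` in the
    cutting order, starting at the mid-lateral landmark.  Spans are half-open
    ``[start, end)``, must be disjoint and tile [0, 360) exactly; a span may
    have ``end_deg > 360`` when it wraps past zero.
    """

    sections: list[tuple[str, float, float]]
    landmark_angle_deg: float = 0.0

    def __post_init__(self):
        if not self.sections:
            raise ValueError("partition needs at least one section")
        widths = []
        for label, start, end in self.sections:
            if not end > start:
                raise ValueError(f"section {label!r}: end must exceed start")
            widths.append(end - start)
        if not np.isclose(sum(widths), FULL_CIRCLE_DEG, atol=1e-6):
            raise ValueError(
                f"section spans must tile 360 degrees exactly; got {sum(widths):g}"
            )
        # contiguity in cutting order
        for (la, _, e0), (lb, s1, _) in zip(self.sections, self.sections[1:]):
            if not np.isclose(wrap_deg(e0), wrap_deg(s1), atol=1e-6):
                raise ValueError(f"gap or overlap between sections {la!r} and {lb!r}")
        self.landmark_angle_deg = float(wrap_deg(self.landmark_angle_deg))

    @property
    def labels(self) -> list[str]:
        return [s[0] for s in self.sections]

    @property
    def widths_deg(self) -> np.ndarray:
        return np.array([e - s for _, s, e in self.sections])

    def span(self, label: str) -> tuple[float, float]:
        for lab, s, e in self.sections:
            if lab == label:
                return s, e
        raise KeyError(label)

    @classmethod
    def equal(cls, n: int, labels=None, landmark_angle_deg: float = 0.0):
        """n equal wedges starting at 0 in the landmark frame."""
        w = FULL_CIRCLE_DEG / n
        labels = labels or [f"s{i + 1}" for i in range(n)]
        return cls(
            [(lab, i * w, (i + 1) * w) for i, lab in enumerate(labels)],
            landmark_angle_deg=landmark_angle_deg,
        )

    def section_containing(self, theta_deg: float) -> str:
        t = wrap_deg(theta_deg)
        for lab, s, e in self.sections:
            if s <= t < e or s <= t + FULL_CIRCLE_DEG < e:
                return lab
        raise ValueError(f"no section contains angle {theta_deg}")  # pragma: no cover


@dataclass
class IntensityImage:
    """A 2-D nonnegative intensity grid with pixel spacing and myocardial mask."""

    pixels: np.ndarray
    pixel_spacing_mm: float
    myocardial_mask: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.myocardial_mask = np.asarray(self.myocardial_mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if self.myocardial_mask.shape != self.pixels.shape:
            raise ValueError("myocardial_mask shape must match pixels")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if not self.myocardial_mask.any():
            raise ValueError("myocardial mask is empty")
        if np.any(self.pixels < 0):
            raise ValueError("pixels must be nonnegative")

    @property
    def shape(self):
        return self.pixels.shape

    def polar(self, center_xy_mm):
        return pixel_polar_mm(self.shape, self.pixel_spacing_mm, center_xy_mm)


@dataclass
class SliceGeometry:
    """LV short-axis contours as polar radius functions on a fixed angle grid.

    ``endo_mm[f, i]`` / ``epi_mm[f, i]`` are radii (mm) from ``center_xy_mm``
    at angle ``theta_deg[i]`` in frame ``f``.  Frame 0 is end-diastole unless
    ``ed_frame_index`` says otherwise.
    """

    center_xy_mm: tuple[float, float]
    theta_deg: np.ndarray
    endo_mm: np.ndarray
    epi_mm: np.ndarray
    ed_frame_index: int = 0
    es_frame_index: int | None = None

    def __post_init__(self):
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        self.endo_mm = np.atleast_2d(np.asarray(self.endo_mm, dtype=float))
        self.epi_mm = np.atleast_2d(np.asarray(self.epi_mm, dtype=float))
        if self.theta_deg.ndim != 1 or self.theta_deg.size < 360:
            raise ValueError("theta grid must be 1-D with at least 360 samples")
        if self.endo_mm.shape != self.epi_mm.shape:
            raise ValueError("endo and epi arrays must have equal shape")
        if self.endo_mm.shape[1] != self.theta_deg.size:
            raise ValueError("contour arrays must match the theta grid")
        if np.any(self.endo_mm < 0):
            raise ValueError("endocardial radius must be nonnegative")
        if np.any(self.epi_mm <= self.endo_mm):
            raise ValueError("epicardial radius must exceed endocardial radius")
        if not (0 <= self.ed_frame_index < self.n_frames):
            raise ValueError("ed_frame_index out of range")
        if self.es_frame_index is not None and not (
            0 <= self.es_frame_index < self.n_frames
        ):
            raise ValueError("es_frame_index out of range")

    @property
    def n_frames(self) -> int:
        return self.endo_mm.shape[0]

    def wall_thickness_mm(self, frame: int) -> np.ndarray:
        self._check_frame(frame)
        return self.epi_mm[frame] - self.endo_mm[frame]

    def cavity_area_mm2(self, frame: int) -> float:
        """Endocardial cavity area via the polar area integral 1/2 ∮ r² dθ."""
        self._check_frame(frame)
        r = self.endo_mm[frame]
        th = np.radians(self.theta_deg)
        r_c = np.append(r, r[0])
        th_c = np.append(th, th[0] + 2 * np.pi)
        return float(0.5 * np.trapezoid(r_c**2, th_c))

    def detect_es_frame(self) -> int:
        areas = [self.cavity_area_mm2(f) for f in range(self.n_frames)]
        return int(np.argmin(areas))

    def _check_frame(self, frame: int):
        if not (0 <= frame < self.n_frames):
            raise IndexError(f"frame {frame} out of range (n_frames={self.n_frames})")


@dataclass
class TissueFractions:
    """Trichrome tissue-class percentages for one histology section."""

    connective_pct: float
    myocyte_pct: float
    adipose_pct: float

    def __post_init__(self):
        total = self.connective_pct + self.myocyte_pct + self.adipose_pct
        for name in ("connective_pct", "myocyte_pct", "adipose_pct"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name} must lie in [0, 100]; got {v}")
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"fractions must sum to 100; got {total}")

    def as_tuple(self):
        return (self.connective_pct, self.myocyte_pct, self.adipose_pct)
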