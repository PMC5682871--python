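"""Synthetic LV phantoms, trichrome sections and multi-animal cohorts.

The phantom emulates the study substrate: one mid-ventricular short-axis
slice of an annular left ventricle carrying an anteroseptal, subendocardial
scar wedge.  The scar grows from the endocardium outward over a fraction of
the wall (the transmurality), carries an elevated fibrosis fraction, appears
hyperintense on the simulated late-gadolinium-enhancement (LGE) image, and
suppresses systolic wall thickening.  Histology sections are rendered as
trichrome-style RGB noise images with known per-pixel class labels, and the
cohort generator produces a multi-animal long-format table driven by a
random-intercept linear model on log-fibrosis so that the mixed-model stage
can be exercised end to end with known ground truth.

All randomness is seeded through explicit ``seed`` fields; identical specs
give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    IntensityImage,
    SliceGeometry,
    circular_distance_deg,
    pixel_polar_mm,
    wrap_deg,
)

#: angular samples of generated contour grids
THETA_SAMPLES = 720
#: angular width (degrees) of the cosine blending ramp at the scar border
SCAR_BORDER_DEG = 10.0

# trichrome rendering: class index -> base RGB
CLASS_CONNECTIVE, CLASS_MYOCYTE, CLASS_ADIPOSE = 0, 1, 2
_CLASS_RGB = {
    CLASS_CONNECTIVE: (60, 60, 190),   # collagen stains blue
    CLASS_MYOCYTE: (190, 55, 70),      # cardiomyocytes stain red
    CLASS_ADIPOSE: (120, 180, 120),    # non-stained cytoplasm, pseudo-green
}
_COLOR_JITTER_SD = 8.0


def _require(cond: bool, field_name: str, message: str):
    if not cond:
        raise ValueError(f"{field_name}: {message}")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic short-axis slice.

    Geometry is a circular annulus (radii in mm); the scar is an angular
    wedge of ``scar_width_deg`` centered on ``scar_center_deg`` reaching
    from the endocardium outward over ``scar_transmurality_frac`` of the
    wall.  ``scar_width_deg = 0`` means no scar.
    """

    image_size_px: tuple[int, int] = (128, 128)
    pixel_spacing_mm: float = 1.5
    center_xy_mm: tuple[float, float] | None = None
    endo_radius_mm: float = 20.0
    epi_radius_mm: float = 30.0
    scar_center_deg: float = 180.0
    scar_width_deg: float = 90.0
    scar_transmurality_frac: float = 0.6
    scar_fibrosis_frac: float = 0.45
    remote_fibrosis_frac: float = 0.03
    lge_scar_intensity: float = 100.0
    lge_remote_intensity: float = 20.0
    noise_sd: float = 0.0
    n_frames: int = 6
    thickening_healthy_mm: float = 4.0
    thickening_scar_mm: float = 0.5
    rv_hinge_angles_deg: tuple[float, float] = (135.0, 225.0)
    seed: int = 0

    def __post_init__(self):
        _require(len(self.image_size_px) == 2 and min(self.image_size_px) >= 8,
                 "image_size_px", "must be an (H, W) pair of at least 8 px")
        _require(self.pixel_spacing_mm > 0, "pixel_spacing_mm", "must be positive")
        _require(self.endo_radius_mm > 0, "endo_radius_mm", "must be positive")
        _require(self.epi_radius_mm > self.endo_radius_mm,
                 "epi_radius_mm", "must exceed endo_radius_mm")
        _require(0 <= self.scar_width_deg <= 360,
                 "scar_width_deg", "must lie in [0, 360]")
        _require(0 <= self.scar_transmurality_frac <= 1,
                 "scar_transmurality_frac", "must lie in [0, 1]")
        _require(0 <= self.scar_fibrosis_frac <= 1,
                 "scar_fibrosis_frac", "must lie in [0, 1]")
        _require(0 <= self.remote_fibrosis_frac <= 1,
                 "remote_fibrosis_frac", "must lie in [0, 1]")
        _require(self.lge_scar_intensity > self.lge_remote_intensity > 0,
                 "lge_scar_intensity", "scar intensity must exceed remote intensity")
        _require(self.noise_sd >= 0, "noise_sd", "must be nonnegative")
        _require(self.n_frames >= 2, "n_frames", "must be at least 2")

    @property
    def center(self) -> tuple[float, float]:
        if self.center_xy_mm is not None:
            return self.center_xy_mm
        h, w = self.image_size_px
        return (w * self.pixel_spacing_mm / 2.0, h * self.pixel_spacing_mm / 2.0)

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class CohortSpec:
    """Random-intercept cohort design on the log-fibrosis scale.

    ``y_ij = beta0 + beta1 * x_ij + u_i + e_ij`` with animal intercepts
    ``u_i ~ N(0, tau00)`` and residuals ``e_ij ~ N(0, sigma2)``; the
    reported fibrosis percentage is ``exp(y_ij)`` capped at 100.
    """

    n_animals: int = 15
    sections_per_animal: int = 8
    beta0: float = 2.0
    beta1: float = 0.0
    sigma2: float = 1.0
    tau00: float = 0.25
    covariate_generator: tuple = ("normal", 0.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        _require(self.n_animals >= 2, "n_animals", "must be at least 2")
        _require(self.sections_per_animal >= 2,
                 "sections_per_animal", "must be at least 2")
        _require(self.sigma2 >= 0, "sigma2", "must be nonnegative")
        _require(self.tau00 >= 0, "tau00", "must be nonnegative")
        name = self.covariate_generator[0]
        _require(name in ("normal", "uniform", "constant"),
                 "covariate_generator", f"unknown distribution {name!r}")

    def replace(self, **kw) -> "CohortSpec":
        return dataclasses.replace(self, **kw)


def scar_wedge_mask(spec: PhantomSpec, radius_mm, angle_deg):
    """Boolean scar region for given per-pixel polar coordinates."""
    if spec.scar_width_deg == 0 or spec.scar_transmurality_frac == 0:
        return np.zeros_like(np.asarray(radius_mm), dtype=bool)
    in_wedge = (
        circular_distance_deg(angle_deg, spec.scar_center_deg)
        <= spec.scar_width_deg / 2.0
    )
    r_outer = spec.endo_radius_mm + spec.scar_transmurality_frac * (
        spec.epi_radius_mm - spec.endo_radius_mm
    )
    return in_wedge & (radius_mm <= r_outer)


def generate_phantom_slice(spec: PhantomSpec):
    """Rasterize one phantom slice.

    Returns ``(geometry, lge_image, fibrosis_field)`` where ``geometry``
    holds the end-diastolic contours, ``lge_image`` the noisy LGE intensity
    grid and ``fibrosis_field`` the noiseless per-pixel fibrosis fraction.
    The LGE signal is a linear map of the local fibrosis fraction taking
    ``remote_fibrosis_frac`` to ``lge_remote_intensity`` and
    ``scar_fibrosis_frac`` to ``lge_scar_intensity``, plus zero-mean
    Gaussian noise clipped at zero.
    """
    r, ang = pixel_polar_mm(spec.image_size_px, spec.pixel_spacing_mm, spec.center)
    myo = (r >= spec.endo_radius_mm) & (r <= spec.epi_radius_mm)
    scar = scar_wedge_mask(spec, r, ang) & myo

    fib = np.zeros(spec.image_size_px, dtype=float)
    fib[myo] = spec.remote_fibrosis_frac
    fib[scar] = spec.scar_fibrosis_frac

    lge = np.zeros(spec.image_size_px, dtype=float)
    span = spec.scar_fibrosis_frac - spec.remote_fibrosis_frac
    if span > 0:
        gain = (spec.lge_scar_intensity - spec.lge_remote_intensity) / span
        lge[myo] = spec.lge_remote_intensity + gain * (
            fib[myo] - spec.remote_fibrosis_frac
        )
    else:  # degenerate contrast: uniform myocardium at the remote level
        lge[myo] = spec.lge_remote_intensity
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        lge = lge + rng.normal(0.0, spec.noise_sd, size=lge.shape)
    lge = np.clip(lge, 0.0, None)

    theta = np.arange(THETA_SAMPLES) * (360.0 / THETA_SAMPLES)
    geometry = SliceGeometry(
        center_xy_mm=spec.center,
        theta_deg=theta,
        endo_mm=np.full((1, THETA_SAMPLES), spec.endo_radius_mm),
        epi_mm=np.full((1, THETA_SAMPLES), spec.epi_radius_mm),
    )
    lge_image = IntensityImage(lge, spec.pixel_spacing_mm, myo)
    fibrosis_field = IntensityImage(fib, spec.pixel_spacing_mm, myo)
    return geometry, lge_image, fibrosis_field


def thickening_profile_mm(spec: PhantomSpec, theta_deg) -> np.ndarray:
    """End-systolic thickening increment per angle with a cosine border ramp.

    Full scar thickening inside the wedge, full healthy thickening beyond
    ``SCAR_BORDER_DEG`` outside it, cosine-blended in between.
    """
    theta_deg = np.asarray(theta_deg, dtype=float)
    if spec.scar_width_deg == 0:
        return np.full(theta_deg.shape, spec.thickening_healthy_mm)
    d = circular_distance_deg(theta_deg, spec.scar_center_deg)
    half = spec.scar_width_deg / 2.0
    w = np.where(
        d <= half,
        1.0,
        np.where(
            d >= half + SCAR_BORDER_DEG,
            0.0,
            0.5 * (1.0 + np.cos(np.pi * (d - half) / SCAR_BORDER_DEG)),
        ),
    )
    return w * spec.thickening_scar_mm + (1.0 - w) * spec.thickening_healthy_mm


def simulate_cine(spec: PhantomSpec) -> SliceGeometry:
    """Contours over a simulated systolic contraction.

    Frame 0 is end-diastole; wall thickness grows linearly over frames to
    the end-systolic thickening profile, the endocardium moving inward while
    the epicardium stays fixed.
    """
    theta = np.arange(THETA_SAMPLES) * (360.0 / THETA_SAMPLES)
    delta = thickening_profile_mm(spec, theta)
    endo0 = np.full(THETA_SAMPLES, spec.endo_radius_mm)
    epi0 = np.full(THETA_SAMPLES, spec.epi_radius_mm)
    if np.any(endo0 - delta <= 0):
        raise ValueError(
            "thickening exceeds the endocardial radius (cavity collapse)"
        )
    s = np.arange(spec.n_frames) / (spec.n_frames - 1)
    endo = endo0[None, :] - s[:, None] * delta[None, :]
    epi = np.broadcast_to(epi0, (spec.n_frames, THETA_SAMPLES)).copy()
    return SliceGeometry(
        center_xy_mm=spec.center,
        theta_deg=theta,
        endo_mm=endo,
        epi_mm=epi,
        ed_frame_index=0,
        es_frame_index=None,
    )


@dataclass
class SyntheticHistoSection:
    """A rendered trichrome section plus its generation ground truth."""

    rgb: np.ndarray            # (H, W, 3) uint8
    tissue_mask: np.ndarray    # all-tissue boolean grid
    labels: np.ndarray         # per-pixel true class indices
    true_fractions: tuple[float, float, float]  # realized (conn, myo, adip)


def generate_histology_image(
    fibrosis_frac: float,
    adipose_frac: float,
    size_px: tuple[int, int] = (100, 100),
    seed: int = 0,
) -> SyntheticHistoSection:
    """Render a trichrome-style section with i.i.d. per-pixel tissue classes.

    Pixels are connective (blue), adipose (pseudo-green) or cardiomyocyte
    (red) with probabilities ``(fibrosis_frac, adipose_frac, remainder)``;
    the realized class fractions are recorded as ground truth.
    """
    if not (0 <= fibrosis_frac <= 1 and 0 <= adipose_frac <= 1):
        raise ValueError("class fractions must lie in [0, 1]")
    if fibrosis_frac + adipose_frac > 1 + 1e-12:
        raise ValueError("fibrosis_frac + adipose_frac must not exceed 1")
    rng = np.random.default_rng(seed)
    p = np.array([fibrosis_frac, 1.0 - fibrosis_frac - adipose_frac, adipose_frac])
    p = np.clip(p, 0.0, 1.0)
    p = p / p.sum()
    labels = rng.choice(3, size=size_px, p=p)
    rgb = np.empty((*size_px, 3), dtype=float)
    for cls, color in _CLASS_RGB.items():
        rgb[labels == cls] = color
    rgb += rng.normal(0.0, _COLOR_JITTER_SD, size=rgb.shape)
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)
    n = labels.size
    true_fractions = (
        float(np.count_nonzero(labels == CLASS_CONNECTIVE) / n),
        float(np.count_nonzero(labels == CLASS_MYOCYTE) / n),
        float(np.count_nonzero(labels == CLASS_ADIPOSE) / n),
    )
    return SyntheticHistoSection(
        rgb=rgb,
        tissue_mask=np.ones(size_px, dtype=bool),
        labels=labels,
        true_fractions=true_fractions,
    )


def _draw_covariate(rng: np.random.Generator, generator: tuple, size: int):
    name, *params = generator
    if name == "normal":
        mean, sd = params
        return rng.normal(mean, sd, size=size)
    if name == "uniform":
        lo, hi = params
        return rng.uniform(lo, hi, size=size)
    if name == "constant":
        return np.full(size, float(params[0]))
    raise ValueError(f"unknown covariate generator {name!r}")  # pragma: no cover


def generate_cohort(cspec: CohortSpec, pspec_template: PhantomSpec | None = None):
    """Draw a multi-animal section table from the random-intercept model.

    Returns ``(table, artifacts)``.  ``table`` is a long-format DataFrame
    with one row per section carrying the covariate, the fibrosis percentage
    (``exp`` of the linear predictor, capped at 100) and the true animal
    intercept.  When a phantom template is supplied, ``artifacts`` maps each
    animal id to a per-animal :class:`PhantomSpec` (template with a spawned
    seed) so that image-level stages can be generated on demand.
    """
    root = np.random.default_rng(cspec.seed)
    u = root.normal(0.0, np.sqrt(cspec.tau00), size=cspec.n_animals)
    rows = []
    artifacts: dict[str, PhantomSpec] = {}
    for i in range(cspec.n_animals):
        animal = f"a{i + 1:03d}"
        x = _draw_covariate(root, cspec.covariate_generator, cspec.sections_per_animal)
        e = root.normal(0.0, np.sqrt(cspec.sigma2), size=cspec.sections_per_animal)
        y = cspec.beta0 + cspec.beta1 * x + u[i] + e
        fib = np.minimum(np.exp(y), 100.0)
        for j in range(cspec.sections_per_animal):
            rows.append(
                {
                    "animal_id": animal,
                    "section_id": f"s{j + 1}",
                    "covariate": float(x[j]),
                    "fibrosis_pct": float(fib[j]),
                    "u_true": float(u[i]),
                    "log_fibrosis_true": float(y[j]),
                }
            )
        if pspec_template is not None:
            artifacts[animal] = pspec_template.replace(
                seed=int(root.integers(0, 2**31 - 1))
            )
    return pd.DataFrame(rows), artifacts
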