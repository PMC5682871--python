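"""Rotational registration of CMR profiles to the histology frame.

The two modalities are aligned through a single landmark: the mid-lateral
point of the LV wall, defined as the point opposite both right-ventricular
hinge points.  Registration acts on sector profiles — a circular rotation
about the LV center — not on pixels, because all downstream comparisons are
section-averaged.

Fractional-sector rotations are resampled spectrally by default (an FFT
phase shift, exact for band-limited profiles and mean-preserving); circular
linear interpolation and nearest-sector assignment are available as
alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SectorProfile, wrap_deg


@dataclass
class LandmarkFrame:
    """An angular reference frame anchored at the mid-lateral landmark."""

    center_xy_mm: tuple[float, float]
    reference_angle_deg: float
    source_tag: str = "cmr"

    def __post_init__(self):
        self.reference_angle_deg = float(wrap_deg(self.reference_angle_deg))


def midlateral_angle(hinge_angle_a_deg: float, hinge_angle_b_deg: float) -> float:
    """Mid-lateral landmark angle from the two RV hinge-point angles.

    The landmark is the circular midpoint of the major arc between the
    hinges — the wall side away from the right ventricle.  Raises when the
    hinges coincide or sit exactly opposite (both arcs equal).
    """
    a = float(wrap_deg(hinge_angle_a_deg))
    b = float(wrap_deg(hinge_angle_b_deg))
    delta = wrap_deg(b - a)
    if np.isclose(delta, 0.0, atol=1e-9) or np.isclose(delta, 360.0, atol=1e-9):
        raise ValueError("hinge angles must be distinct")
    if np.isclose(delta, 180.0, atol=1e-9):
        raise ValueError("hinges are diametrically opposite: landmark ambiguous")
    mid_ccw_arc = a + delta / 2.0  # midpoint of the a -> b counterclockwise arc
    if delta < 180.0:  # that arc is the minor (RV) side; landmark is opposite
        mid_ccw_arc += 180.0
    return float(wrap_deg(mid_ccw_arc))


def _fourier_shift(values: np.ndarray, shift_sectors: float) -> np.ndarray:
    k = values.size
    freq = np.fft.fftfreq(k)
    spectrum = np.fft.fft(values) * np.exp(-2j * np.pi * freq * shift_sectors)
    return np.fft.ifft(spectrum).real


def _linear_shift(values: np.ndarray, shift_sectors: float) -> np.ndarray:
    k = values.size
    base = np.floor(shift_sectors)
    frac = shift_sectors - base
    rolled = np.roll(values, int(base))
    if frac == 0:
        return rolled
    return (1.0 - frac) * rolled + frac * np.roll(values, int(base) + 1)


def rotate_profile(
    profile: SectorProfile,
    from_frame: LandmarkFrame,
    to_frame: LandmarkFrame,
    method: str = "fourier",
) -> SectorProfile:
    """Rotate a sector profile between landmark frames.

    The rotation angle is ``Δθ = reference_angle(to) − reference_angle(from)``:
    a feature at angle ``θ`` in the source frame appears at ``θ + Δθ`` in
    the target frame.  Integer-sector shifts are exact circular rolls;
    fractional shifts are resampled per ``method`` (``"fourier"``,
    ``"linear"`` or ``"nearest"``).
    """
    delta_deg = to_frame.reference_angle_deg - from_frame.reference_angle_deg
    shift = delta_deg / profile.sector_width_deg
    values = profile.values
    if np.isclose(shift, round(shift), atol=1e-12):
        out = np.roll(values, int(round(shift)) % profile.K)
    elif method == "fourier":
        out = _fourier_shift(values, shift)
    elif method == "linear":
        out = _linear_shift(values, shift)
    elif method == "nearest":
        out = np.roll(values, int(round(shift)) % profile.K)
    else:
        raise ValueError(f"unknown rotation method {method!r}")
    return profile.replace(values=out, frame=to_frame.source_tag)
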