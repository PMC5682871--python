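"""Wall-thickening and strain sector profiles from cine contour series.

Wall thickness is the ray distance from the endocardial to the epicardial
contour along spokes from the fixed LV center, averaged per angular sector
(60 sectors in study mode).  Strain is computed geometrically from the
contours rather than by gray-value feature tracking: circumferential strain
is the Lagrangian change of the sector's midwall arc length and radial
strain the Lagrangian change of the sector's mean wall thickness, both
end-systole vs. the end-diastolic reference (48 sectors in study mode).
Shortening is negative, thickening positive.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import SectionPartition, SectorProfile, sector_index, wrap_deg


def _sector_means(values: np.ndarray, theta_deg: np.ndarray, K: int) -> np.ndarray:
    idx = sector_index(theta_deg, K)
    sums = np.bincount(idx, weights=values, minlength=K)
    counts = np.bincount(idx, minlength=K)
    if np.any(counts == 0):
        raise ValueError(
            f"angular grid too coarse for K={K}: some sectors hold no samples"
        )
    return sums / counts


def wall_thickness_profile(geom, frame: int, K: int = 60) -> SectorProfile:
    """Sector-mean wall thickness (mm) of one frame."""
    wt = geom.wall_thickness_mm(frame)  # raises IndexError for a bad frame
    return SectorProfile(
        _sector_means(wt, geom.theta_deg, K),
        quantity="wall_thickness",
        units="mm",
        frame="native",
    )


def end_systolic_wt(geom, K: int = 60) -> SectorProfile:
    """Wall-thickness profile at end-systole.

    End-systole is ``geom.es_frame_index`` when set, otherwise the frame of
    minimal endocardial cavity area.  A fully static series (all frames
    identical) yields the last frame with a warning.
    """
    if geom.n_frames < 2:
        raise ValueError("end-systolic thickness needs at least two frames")
    es = geom.es_frame_index
    if es is None:
        if np.allclose(geom.endo_mm, geom.endo_mm[0]) and np.allclose(
            geom.epi_mm, geom.epi_mm[0]
        ):
            warnings.warn(
                "all frames identical; taking the last frame as end-systole",
                stacklevel=2,
            )
            es = geom.n_frames - 1
        else:
            es = geom.detect_es_frame()
    return wall_thickness_profile(geom, es, K=K)


def strain_profiles(geom, K: int = 48):
    """Circumferential strain, radial strain and FT-style wall thickness.

    Returns ``(ecc, err, wt_ft)`` sector profiles at end-systole with
    end-diastole as the Lagrangian reference:

    * ``ecc`` = 100 * (L_es - L_ed) / L_ed, L the sector midwall arc length
      (midwall radius = (endo + epi) / 2 on a uniform angle grid);
    * ``err`` = 100 * (T_es - T_ed) / T_ed, T the sector mean wall thickness;
    * ``wt_ft`` = T_es in mm.
    """
    if geom.n_frames < 2:
        raise ValueError("strain needs at least two frames")
    ed = geom.ed_frame_index
    es = geom.es_frame_index
    if es is None:
        es = geom.detect_es_frame()

    def per_frame(frame):
        mid = 0.5 * (geom.endo_mm[frame] + geom.epi_mm[frame])
        wt = geom.epi_mm[frame] - geom.endo_mm[frame]
        # uniform angular grid: sector arc length ∝ sector-mean midwall radius
        return (
            _sector_means(mid, geom.theta_deg, K),
            _sector_means(wt, geom.theta_deg, K),
        )

    mid_ed, wt_ed = per_frame(ed)
    mid_es, wt_es = per_frame(es)
    if np.any(mid_ed <= 0) or np.any(wt_ed <= 0):
        raise ValueError("degenerate end-diastolic reference (zero length)")
    ecc = SectorProfile(
        100.0 * (mid_es - mid_ed) / mid_ed,
        quantity="circumferential_strain", units="%", frame="native",
    )
    err = SectorProfile(
        100.0 * (wt_es - wt_ed) / wt_ed,
        quantity="radial_strain", units="%", frame="native",
    )
    wt_ft = SectorProfile(
        wt_es, quantity="wall_thickness_ft", units="mm", frame="native"
    )
    return ecc, err, wt_ft


def _interval_overlap(a0, a1, b0, b1):
    return max(0.0, min(a1, b1) - max(a0, b0))


def average_to_sections(
    profile: SectorProfile, partition: SectionPartition
) -> pd.Series:
    """Angular-overlap-weighted section means of a sector profile.

    Each section value is the mean of the sector values weighted by the
    angular overlap between the sector and the section span; the weights of
    a section sum to its angular width, so the span-weighted mean of the
    section values equals the profile mean.
    """
    K = profile.K
    w = profile.sector_width_deg
    sector_bounds = [(k * w, (k + 1) * w) for k in range(K)]
    out = {}
    for label, start, end in partition.sections:
        # unroll the (possibly wrapping) section span into [0, 360) pieces
        pieces = []
        s, e = wrap_deg(start), wrap_deg(start) + (end - start)
        if e <= 360.0:
            pieces.append((s, e))
        else:
            pieces.append((s, 360.0))
            pieces.append((0.0, e - 360.0))
        total_w = 0.0
        acc = 0.0
        for k, (b0, b1) in enumerate(sector_bounds):
            ow = sum(_interval_overlap(p0, p1, b0, b1) for p0, p1 in pieces)
            if ow > 0:
                acc += ow * profile.values[k]
                total_w += ow
        if total_w <= 0:
            raise ValueError(f"section {label!r} overlaps no sector")
        out[label] = acc / total_w
    return pd.Series(out, name=profile.quantity)
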