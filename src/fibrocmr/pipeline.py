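"""End-to-end orchestration: phantom cohort → quantification → mixed models.

In synthetic mode the pipeline generates a multi-animal phantom cohort,
pushes every animal through the histology and CMR quantification stages,
registers the CMR sector profiles to the histology frame via the
mid-lateral landmark, averages them over the histology sections, and fits
the null and full mixed models to produce the explained-variance table.  In
user-data mode it consumes a prepared long-format section table (CSV) and
runs the statistics stage; image-level user data is handled by composing
the library modules directly.

The synthetic cohort emulates the study conditions: ~15 animals, 7–8
histology wedge sections per slice, an anteroseptal subendocardial scar of
variable transmural extent, LGE signal monotone in local fibrosis,
thickening suppressed in scar (saturating once half the wall is scarred),
and animal-level random variation of fibrosis on the log scale.  The
functional exports carry fixed measurement jitter emulating contour-tracing
and feature-tracking variability; it is a property of the emulated
measurement modalities, separate from the LGE image-noise dial.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cine import average_to_sections, end_systolic_wt, strain_profiles
from .core import SectionPartition, fill_missing_sectors, wrap_deg
from .histology import HistoSectionImage, section_fibrosis
from .lge import (
    apply_manual_correction,
    fwhm_mask,
    msi_profile,
    remote_region_from_span,
    sd_remote_mask,
    transmurality_profile,
)
from .registration import LandmarkFrame, midlateral_angle, rotate_profile
from .stats import DEFAULT_LOG_OFFSET, compare_all, log_fibrosis
from .synthetic import PhantomSpec, generate_histology_image, generate_phantom_slice, simulate_cine

logger = logging.getLogger(__name__)

#: covariates exported by the synthetic pipeline, in study-table order
DEFAULT_COVARIATES = [
    "es_wt_mm",
    "ft_wt_mm",
    "err_pct",
    "ecc_pct",
    "tm_sd2_pct",
    "tm_sd3_pct",
    "tm_sd5_pct",
    "tm_sd2m_pct",
    "tm_sd3m_pct",
    "tm_sd5m_pct",
    "tm_fwhm_pct",
    "msi_au",
]

#: transmurality above which systolic thickening is fully lost
THICKENING_LOSS_TM = 0.5


@dataclass(frozen=True)
class SyntheticCohortParams:
    """Study-condition knobs of the synthetic cohort.

    Ranges are per-animal draws.  ``*_noise`` fields are the fixed
    measurement jitters of the emulated modalities; ``lge_noise_sd`` is the
    image noise of the LGE acquisition; the log-scale SDs perturb the
    histological fibrosis response.
    """

    n_animals: int = 15
    sections_choices: tuple[int, ...] = (7, 8)
    endo_radius_mm: float = 20.0
    epi_radius_mm: float = 30.0
    pixel_spacing_mm: float = 1.5
    image_size_px: tuple[int, int] = (128, 128)
    lge_remote_intensity: float = 20.0
    lge_scar_intensity: float = 100.0
    lge_noise_sd: float = 5.0
    transmurality_range: tuple[float, float] = (0.15, 0.95)
    scar_width_range_deg: tuple[float, float] = (60.0, 120.0)
    scar_center_range_deg: tuple[float, float] = (150.0, 210.0)  # anteroseptal
    scar_fibrosis_range: tuple[float, float] = (0.30, 0.57)
    remote_fibrosis_frac: float = 0.03
    thickening_healthy_mean_mm: float = 4.0
    thickening_healthy_sd_mm: float = 0.5
    n_frames: int = 6
    wt_seg_noise_mm: float = 0.5
    ft_wt_noise_mm: float = 1.0
    ecc_noise_pct: float = 4.0
    err_noise_pct: float = 15.0
    animal_log_sd: float = 0.25
    section_log_sd: float = 0.30
    histo_size_px: tuple[int, int] = (100, 100)
    adipose_frac: float = 0.05
    remote_half_width_deg: float = 30.0
    manual_correction_margin_deg: float = 15.0

    def replace(self, **kw) -> "SyntheticCohortParams":
        return dataclasses.replace(self, **kw)

    @classmethod
    def noiseless(cls, **kw) -> "SyntheticCohortParams":
        """High-contrast cohort without LGE image noise or fibrosis noise.

        The fixed measurement jitter of the functional exports remains:
        it belongs to the emulated modalities, not to the image.
        """
        base = dict(lge_noise_sd=0.0, animal_log_sd=0.0, section_log_sd=0.0)
        base.update(kw)
        return cls(**base)


def _wedge_mean(field, angle_lm_deg, start, end):
    width = end - start
    sel = field.myocardial_mask & (wrap_deg(angle_lm_deg - start) < width)
    if not sel.any():
        return 0.0
    return float(field.pixels[sel].mean())


def _animal_rows(params: SyntheticCohortParams, animal_id: str, rng, scar_methods):
    """Quantify one synthetic animal end to end; returns its section rows."""
    phi = rng.uniform(0.0, 360.0)
    tm = rng.uniform(*params.transmurality_range)
    width = rng.uniform(*params.scar_width_range_deg)
    center_lm = rng.uniform(*params.scar_center_range_deg)
    fib_scar = rng.uniform(*params.scar_fibrosis_range)
    h_mm = max(1.0, rng.normal(params.thickening_healthy_mean_mm,
                               params.thickening_healthy_sd_mm))
    scar_th = h_mm * max(0.0, 1.0 - tm / THICKENING_LOSS_TM)
    spec = PhantomSpec(
        image_size_px=params.image_size_px,
        pixel_spacing_mm=params.pixel_spacing_mm,
        endo_radius_mm=params.endo_radius_mm,
        epi_radius_mm=params.epi_radius_mm,
        scar_center_deg=wrap_deg(center_lm + phi),
        scar_width_deg=width,
        scar_transmurality_frac=tm,
        scar_fibrosis_frac=fib_scar,
        remote_fibrosis_frac=params.remote_fibrosis_frac,
        lge_scar_intensity=params.lge_scar_intensity,
        lge_remote_intensity=params.lge_remote_intensity,
        noise_sd=params.lge_noise_sd,
        n_frames=params.n_frames,
        thickening_healthy_mm=h_mm,
        thickening_scar_mm=scar_th,
        rv_hinge_angles_deg=(wrap_deg(phi + 135.0), wrap_deg(phi + 225.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    geom = simulate_cine(spec)
    _, lge, fib_field = generate_phantom_slice(spec)

    landmark = midlateral_angle(*spec.rv_hinge_angles_deg)
    cmr_frame = LandmarkFrame(spec.center, landmark, "cmr")
    histo_frame = LandmarkFrame(spec.center, 0.0, "histology")

    n_sec = int(rng.choice(params.sections_choices))
    raw = rng.uniform(0.7, 1.3, size=n_sec)
    edges = np.concatenate([[0.0], np.cumsum(raw / raw.sum() * 360.0)])
    edges[-1] = 360.0
    partition = SectionPartition(
        [(f"s{j + 1}", edges[j], edges[j + 1]) for j in range(n_sec)]
    )

    def registered_sections(profile):
        # bounded linear resampling: %TM and MSI maps are discontinuous at the
        # scar border, where a spectral shift would ring and overshoot
        profile = profile.replace(values=fill_missing_sectors(profile.values))
        return average_to_sections(
            rotate_profile(profile, cmr_frame, histo_frame, method="linear"),
            partition,
        )

    wt60 = registered_sections(end_systolic_wt(geom, K=60))
    ecc, err, wt_ft = strain_profiles(geom, K=48)
    ecc_s = registered_sections(ecc)
    err_s = registered_sections(err)
    ftwt_s = registered_sections(wt_ft)

    remote = remote_region_from_span(
        lge, geom, landmark, params.remote_half_width_deg
    )
    _, ang = lge.polar(spec.center)
    from .core import circular_distance_deg

    exclusion = lge.myocardial_mask & (
        circular_distance_deg(ang, spec.scar_center_deg)
        > width / 2.0 + params.manual_correction_margin_deg
    )
    masks = {}
    if "fwhm" in scar_methods:
        masks["tm_fwhm_pct"] = fwhm_mask(lge)
    for n_sd in (2, 3, 5):
        base = None
        if f"sd{n_sd}" in scar_methods or f"sd{n_sd}m" in scar_methods:
            base = sd_remote_mask(lge, remote, n_sd)
        if f"sd{n_sd}" in scar_methods:
            masks[f"tm_sd{n_sd}_pct"] = base
        if f"sd{n_sd}m" in scar_methods:
            masks[f"tm_sd{n_sd}m_pct"] = apply_manual_correction(base, exclusion)
    tm_sections = {
        name: registered_sections(transmurality_profile(m, geom, K=360))
        for name, m in masks.items()
    }
    msi_s = registered_sections(msi_profile(lge, geom, K=360))

    u_i = rng.normal(0.0, params.animal_log_sd) if params.animal_log_sd > 0 else 0.0
    ang_lm = wrap_deg(ang - landmark)
    rows = []
    for label, start, end in partition.sections:
        true_frac = _wedge_mean(fib_field, ang_lm, start, end)
        e_ij = (
            rng.normal(0.0, params.section_log_sd)
            if params.section_log_sd > 0
            else 0.0
        )
        frac = min(true_frac * float(np.exp(u_i + e_ij)), 1.0 - params.adipose_frac)
        histo = generate_histology_image(
            frac,
            params.adipose_frac,
            size_px=params.histo_size_px,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        fractions = section_fibrosis(
            HistoSectionImage(histo.rgb, histo.tissue_mask, label)
        )
        row = {
            "animal_id": animal_id,
            "section_id": label,
            "fibrosis_pct": fractions.connective_pct,
            "true_fibrosis_pct": 100.0 * true_frac,
            "es_wt_mm": wt60[label] + rng.normal(0.0, params.wt_seg_noise_mm),
            "ft_wt_mm": ftwt_s[label] + rng.normal(0.0, params.ft_wt_noise_mm),
            "ecc_pct": ecc_s[label] + rng.normal(0.0, params.ecc_noise_pct),
            "err_pct": err_s[label] + rng.normal(0.0, params.err_noise_pct),
            "msi_au": msi_s[label],
        }
        for name, series in tm_sections.items():
            row[name] = series[label]
        rows.append(row)
    return rows


def build_synthetic_cohort(
    params: SyntheticCohortParams,
    seed: int = 0,
    scar_methods=("fwhm", "sd2", "sd3", "sd5", "sd2m", "sd3m", "sd5m"),
) -> pd.DataFrame:
    """Generate and quantify a whole synthetic cohort; one row per section."""
    children = np.random.SeedSequence(seed).spawn(params.n_animals)
    rows = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        rows.extend(_animal_rows(params, f"a{i + 1:03d}", rng, set(scar_methods)))
    return pd.DataFrame(rows)


def stratify_by_transmurality(
    table: pd.DataFrame,
    tm_covariate: str = "tm_fwhm_pct",
    bin_edges: tuple = (0.0, 25.0, 50.0, 75.0, 100.0),
    value_columns: tuple = ("fibrosis_pct", "ft_wt_mm", "err_pct", "ecc_pct"),
) -> pd.DataFrame:
    """Median/quartile summaries of fibrosis and function per %TM subgroup.

    Sections with %TM exactly zero form their own group; positive values
    fall into half-open bins ``(edge_i, edge_{i+1}]``.  Every section lands
    in exactly one bin; empty bins are reported with ``n = 0``.
    """
    if tm_covariate not in table.columns:
        raise ValueError(f"missing transmurality covariate {tm_covariate!r}")
    tm = table[tm_covariate].to_numpy(dtype=float)
    labels = ["0"] + [
        f"{lo:g}-{hi:g}" for lo, hi in zip(bin_edges, bin_edges[1:])
    ]
    assignment = np.full(len(table), "", dtype=object)
    assignment[tm == 0] = "0"
    for lo, hi in zip(bin_edges, bin_edges[1:]):
        assignment[(tm > lo) & (tm <= hi)] = f"{lo:g}-{hi:g}"
    out_rows = []
    present = [c for c in value_columns if c in table.columns]
    for lab in labels:
        sub = table.loc[assignment == lab]
        row = {"tm_bin": lab, "n": len(sub)}
        for col in present:
            if len(sub):
                q1, med, q3 = np.percentile(sub[col], [25, 50, 75])
            else:
                q1 = med = q3 = np.nan
            row[f"{col}_median"] = med
            row[f"{col}_q1"] = q1
            row[f"{col}_q3"] = q3
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def run(config: dict, output_dir=None) -> tuple[dict, pd.DataFrame]:
    """Execute the full pipeline from a config mapping.

    Returns ``(manifest, results)`` and, when an output directory is given
    (in the config or as an argument), writes the section table, the
    explained-variance results, the transmurality stratification and a JSON
    manifest there.  Synthetic-mode reruns with the same config are
    bit-identical apart from the manifest timestamp.
    """
    mode = config.get("mode", "synthetic")
    seed = int(config.get("seed", 0))
    stats_cfg = config.get("stats", {})
    covariates = stats_cfg.get("covariates")
    offset = float(stats_cfg.get("response_offset", DEFAULT_LOG_OFFSET))
    reml = bool(stats_cfg.get("reml", False))
    scar_methods = tuple(
        config.get("scar_methods", ("fwhm", "sd2", "sd3", "sd5", "sd2m", "sd3m", "sd5m"))
    )
    if not scar_methods:
        raise ValueError("scar method list must be nonempty")

    if mode == "synthetic":
        params = SyntheticCohortParams(**config.get("synthetic", {}))
        logger.info("generating synthetic cohort (%d animals)", params.n_animals)
        table = build_synthetic_cohort(params, seed=seed, scar_methods=scar_methods)
        if covariates is None:
            covariates = [c for c in DEFAULT_COVARIATES if c in table.columns]
    elif mode == "user-data":
        path = Path(config["section_table"])
        if not path.exists():
            raise FileNotFoundError(f"section table not found: {path}")
        table = pd.read_csv(path)
        if covariates is None:
            covariates = [
                c
                for c in table.columns
                if c not in ("animal_id", "section_id", "fibrosis_pct")
            ]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    table = log_fibrosis(table, offset=offset)
    results = compare_all(table, list(covariates), reml=reml)
    tm_col = config.get("stratify", {}).get("tm_covariate", "tm_fwhm_pct")
    strata = (
        stratify_by_transmurality(table, tm_col) if tm_col in table.columns else None
    )

    manifest = {
        "package": "fibrocmr",
        "version": __version__,
        "mode": mode,
        "seed": seed,
        "config_sha256": _config_hash(config),
        "n_sections": int(len(table)),
        "n_animals": int(table["animal_id"].nunique()),
        "null_total": float(results.attrs["null_total"]),
        "covariates": list(covariates),
        "log_offset": offset,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }

    out = output_dir or config.get("output_dir")
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "section_table.csv", index=False)
        results.to_csv(out / "results.csv", index=False)
        if strata is not None:
            strata.to_csv(out / "stratified.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest, results
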