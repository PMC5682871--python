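"""Trichrome tissue-class quantification and the angular LV fibrosis map.

Sections stained with Masson's trichrome separate into three color classes:
collagen (connective tissue) stains blue, cardiomyocytes stain red, and
non-stained cytoplasm (treated as the adipose class) reads as a
low-saturation pseudo-green.  Classification is a fixed hue/saturation
partition in HSV space — adequate for well-separated stains and for the
synthetic sections of :mod:`fibrocmr.synthetic`; it performs no stain
deconvolution or normalization.  The epicardium is excluded through the
``tissue_mask`` supplied with each section image, never detected here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

from .core import SectionPartition, SectorProfile, TissueFractions

LABEL_CONNECTIVE, LABEL_MYOCYTE, LABEL_ADIPOSE = 0, 1, 2
LABEL_BACKGROUND = -1

# hue is on [0, 1); red wraps around zero
RED_HUE_MAX = 0.17
BLUE_HUE_MIN = 0.50
BLUE_HUE_MAX = 0.83
LOW_SATURATION = 0.15


@dataclass
class HistoSectionImage:
    """One histology section: RGB pixels, tissue mask, section label."""

    rgb: np.ndarray
    tissue_mask: np.ndarray
    section_label: str = ""

    def __post_init__(self):
        self.rgb = np.asarray(self.rgb)
        self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be an (H, W, 3) array")
        if self.tissue_mask.shape != self.rgb.shape[:2]:
            raise ValueError("tissue_mask shape must match the image")
        if not self.tissue_mask.any():
            raise ValueError("section has no tissue pixels")


def classify_pixels(img: HistoSectionImage) -> np.ndarray:
    """Label every tissue pixel as connective, myocyte or adipose.

    Blue-dominant hues map to connective tissue, red-dominant hues to
    cardiomyocytes, and green-dominant or low-saturation pixels to the
    adipose/pseudo-green class.  Non-tissue pixels get ``LABEL_BACKGROUND``.
    """
    if not img.tissue_mask.any():  # defensive; constructor already rejects
        raise ValueError("section has no tissue pixels")
    hsv = rgb2hsv(np.asarray(img.rgb, dtype=float) / 255.0)
    hue, sat = hsv[..., 0], hsv[..., 1]
    labels = np.full(img.rgb.shape[:2], LABEL_BACKGROUND, dtype=np.int8)
    adipose = (sat < LOW_SATURATION) | ((hue >= RED_HUE_MAX) & (hue < BLUE_HUE_MIN))
    connective = (~adipose) & (hue >= BLUE_HUE_MIN) & (hue < BLUE_HUE_MAX)
    myocyte = (~adipose) & (~connective)
    labels[img.tissue_mask & adipose] = LABEL_ADIPOSE
    labels[img.tissue_mask & connective] = LABEL_CONNECTIVE
    labels[img.tissue_mask & myocyte] = LABEL_MYOCYTE
    return labels


def section_fibrosis(img: HistoSectionImage) -> TissueFractions:
    """Tissue-class percentages of one section (they sum to 100 exactly)."""
    labels = classify_pixels(img)
    tissue = labels[img.tissue_mask]
    n = tissue.size
    return TissueFractions(
        connective_pct=100.0 * np.count_nonzero(tissue == LABEL_CONNECTIVE) / n,
        myocyte_pct=100.0 * np.count_nonzero(tissue == LABEL_MYOCYTE) / n,
        adipose_pct=100.0 * np.count_nonzero(tissue == LABEL_ADIPOSE) / n,
    )


def build_overview(
    fractions: dict[str, TissueFractions], partition: SectionPartition
) -> SectorProfile:
    """Standardized 360-sector fibrosis map from per-section fractions.

    Each 1-degree sector carries the connective-tissue percentage of the
    section whose span contains the sector center, giving the
    piecewise-constant schematic LV overview used for comparison with the
    CMR exports.
    """
    missing = [lab for lab in partition.labels if lab not in fractions]
    if missing:
        raise ValueError(f"missing fibrosis records for sections: {missing}")
    values = np.empty(360, dtype=float)
    for k in range(360):
        lab = partition.section_containing(k + 0.5)
        values[k] = fractions[lab].connective_pct
    return SectorProfile(
        values, quantity="fibrosis", units="%", frame="histology"
    )
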