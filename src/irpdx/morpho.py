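"""Whole-slide invasiveness morphometry.

Reproduces a QuPath-style measurement sequence on binary masks of stained
sections (all radii are physical distances, converted to pixels by the
slide's µm-per-pixel scale):

- tissue is eroded by 35 µm to exclude extracerebral tumour;
- the tumour core is a morphological opening of the tumour (hVim) mask by
  10 µm, with connected components smaller than 10,000 µm² removed;
- the gross tumour is a morphological closing of the tumour mask by 75 µm
  (bridging gaps up to 150 µm), keeping only components that contain a
  core component;
- metrics: %hVim area (tumour / tissue area), invasiveness index
  (gross area / core area) and positive-cell density per mm² of hVim.

Erosions/dilations use exact Euclidean disk structuring elements computed
via distance transforms, which is both exact and fast at large radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from skimage.measure import label, regionprops

TISSUE_ERODE_UM = 35.0
CORE_OPEN_UM = 10.0
MIN_CORE_AREA_UM2 = 10_000.0
GROSS_CLOSE_UM = 75.0
CONNECTIVITY = 2  # 8-connected


@dataclass
class SlideMasks:
    """Binary rasters of one stained section with physical scale.

    ``tissue`` and ``tumour`` are boolean arrays of the same shape;
    ``centroids`` are (row, col) pixel coordinates of positive cells;
    ``um_per_px`` is the side length of a pixel in µm.
    """

    tissue: np.ndarray
    tumour: np.ndarray
    um_per_px: float
    centroids: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.tissue.shape != self.tumour.shape:
            raise ValueError("tissue and tumour masks must share a shape")
        self.tissue = np.asarray(self.tissue, dtype=bool)
        self.tumour = np.asarray(self.tumour, dtype=bool)
        c = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        if len(c) and (
            (c < -0.5).any()
            or (c[:, 0] > self.tissue.shape[0] - 0.5).any()
            or (c[:, 1] > self.tissue.shape[1] - 0.5).any()
        ):
            raise ValueError("centroids outside image bounds")
        self.centroids = c


def _radius_px(radius_um: float, um_per_px: float) -> int:
    # round half up, for cross-platform determinism
    return int(np.floor(radius_um / um_per_px + 0.5))


def erode(mask: np.ndarray, radius_um: float, um_per_px: float) -> np.ndarray:
    """Euclidean-disk erosion by a physical radius."""
    r = _radius_px(radius_um, um_per_px)
    if r == 0:
        return mask.copy()
    return distance_transform_edt(mask) > r


def dilate(mask: np.ndarray, radius_um: float, um_per_px: float) -> np.ndarray:
    """Euclidean-disk dilation by a physical radius."""
    r = _radius_px(radius_um, um_per_px)
    if r == 0:
        return mask.copy()
    return distance_transform_edt(~mask) <= r


def opening(mask: np.ndarray, radius_um: float, um_per_px: float) -> np.ndarray:
    return dilate(erode(mask, radius_um, um_per_px), radius_um, um_per_px)


def closing(mask: np.ndarray, radius_um: float, um_per_px: float) -> np.ndarray:
    return erode(dilate(mask, radius_um, um_per_px), radius_um, um_per_px)


def area_um2(mask: np.ndarray, um_per_px: float) -> float:
    return float(mask.sum()) * um_per_px**2


def prepare_tissue(masks: SlideMasks, erode_um: float = TISSUE_ERODE_UM) -> np.ndarray:
    """Erode the tissue annotation by 35 µm."""
    out = erode(masks.tissue, erode_um, masks.um_per_px)
    if not out.any():
        raise ValueError("tissue erosion emptied the mask")
    return out


def tumour_core(
    masks: SlideMasks,
    open_um: float = CORE_OPEN_UM,
    min_area_um2: float = MIN_CORE_AREA_UM2,
) -> np.ndarray:
    """Open the tumour mask by 10 µm and drop components < 10,000 µm²."""
    core = opening(masks.tumour, open_um, masks.um_per_px)
    lab = label(core, connectivity=CONNECTIVITY)
    px_area = masks.um_per_px**2
    out = np.zeros_like(core)
    for region in regionprops(lab):
        if region.area * px_area >= min_area_um2:
            out[lab == region.label] = True
    return out


def gross_components(
    masks: SlideMasks, close_um: float = GROSS_CLOSE_UM
) -> tuple[np.ndarray, np.ndarray]:
    """Gross-tumour mask and component labels.

    The mask is the 75 µm closing of the tumour mask.  Component identity
    is assigned at the dilation stage, where nearby objects merge (gaps up
    to 2x the radius are filled); the subsequent erosion restores border
    distance but does not re-split a merged object.  Returns the closed
    mask and an integer label image over it.
    """
    dil = dilate(masks.tumour, close_um, masks.um_per_px)
    lab = label(dil, connectivity=CONNECTIVITY)
    gross = erode(dil, close_um, masks.um_per_px)
    return gross, np.where(gross, lab, 0)


def gross_tumour(
    masks: SlideMasks, core: np.ndarray, close_um: float = GROSS_CLOSE_UM
) -> np.ndarray:
    """Close the tumour mask by 75 µm; keep components containing core."""
    gross, lab = gross_components(masks, close_um)
    keep_labels = np.unique(lab[core & (lab > 0)])
    return np.isin(lab, keep_labels[keep_labels > 0])


def indices(
    tissue: np.ndarray,
    tumour: np.ndarray,
    core: np.ndarray,
    gross: np.ndarray,
    centroids: np.ndarray,
    um_per_px: float,
) -> pd.DataFrame:
    """Morphometric indices from the prepared regions.

    Returns %hVim area, invasiveness index (gross/core area, NaN when the
    core is empty) and positive-cell density per mm² of hVim (NaN when the
    tumour mask is empty).
    """
    a_tissue = area_um2(tissue, um_per_px)
    a_tumour = area_um2(tumour, um_per_px)
    a_core = area_um2(core, um_per_px)
    a_gross = area_um2(gross, um_per_px)
    pct_hvim = 100.0 * a_tumour / a_tissue if a_tissue > 0 else np.nan
    invasiveness = a_gross / a_core if a_core > 0 else np.nan
    n_pos = len(np.asarray(centroids).reshape(-1, 2))
    density = n_pos / (a_tumour / 1e6) if a_tumour > 0 else np.nan
    return pd.DataFrame(
        {
            "tissue_area_um2": [a_tissue],
            "hvim_area_um2": [a_tumour],
            "core_area_um2": [a_core],
            "gross_area_um2": [a_gross],
            "pct_hvim_area": [pct_hvim],
            "invasiveness_index": [invasiveness],
            "cells_per_mm2_hvim": [density],
        }
    )


def analyse(masks: SlideMasks) -> pd.DataFrame:
    """Full morphometry pipeline on one slide."""
    tissue = prepare_tissue(masks)
    core = tumour_core(masks)
    gross = gross_tumour(masks, core)
    return indices(tissue, masks.tumour, core, gross, masks.centroids, masks.um_per_px)
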