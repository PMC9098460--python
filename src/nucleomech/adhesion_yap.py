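"""Focal-adhesion particle quantification and the YAP-TAZ N/C ratio.

Focal adhesions (vinculin puncta) are measured on the best-focus
z-plane: moment-preserving auto-threshold, connected components, and a
minimum particle size of 25 px² — the classic macro's particle-analysis
cutoff.  The YAP-TAZ nuclear/cytoplasmic ratio compares the mean
intensity of two equal-area regions: one eroded inward from the nucleus
and one grown as a band immediately outside it, mirroring the manual
equal-area ROI protocol but constructed deterministically from the
nucleus mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .images import RasterImage, ImageStack
from .segmentation import threshold_moments

__all__ = [
    "AdhesionRecord",
    "YapRatioRecord",
    "select_best_plane",
    "segment_adhesions",
    "mean_adhesion_area",
    "yap_nc_ratio",
]

DEFAULT_MIN_AREA_PX = 25  # particle-analysis size cutoff, px²


@dataclass(frozen=True)
class AdhesionRecord:
    particle_id: int
    area_px: int
    area_um2: float
    centroid_um: tuple[float, float]   # (x, y)
    mean_intensity: float
    plane: int = 0


@dataclass(frozen=True)
class YapRatioRecord:
    cell_id: str
    nuclear_mean: float
    cytoplasmic_mean: float
    ratio: float
    region_area_px: int


def select_best_plane(stack: ImageStack, channel: int | str = 0
                      ) -> tuple[int, pd.DataFrame]:
    """Pick the in-focus plane by normalized variance (variance/mean²).

    Returns (plane index, per-plane score table); ties go to the lowest
    index.  Raises on stacks whose every plane is zero.
    """
    scores = []
    for z in range(stack.n_z):
        px = stack.plane(z, channel).pixels
        mu = px.mean()
        scores.append(px.var() / mu ** 2 if mu > 0 else np.nan)
    table = pd.DataFrame({"z": np.arange(stack.n_z), "focus_score": scores})
    if np.all(np.isnan(scores)):
        raise ValueError("all planes are zero: no focus score defined")
    best = int(np.nanargmax(scores))
    return best, table


def segment_adhesions(image: RasterImage,
                      min_area_px: int = DEFAULT_MIN_AREA_PX,
                      plane: int = 0) -> list[AdhesionRecord]:
    """Segment bright particles and measure each one.

    Moment-preserving threshold -> connected components -> keep
    particles of at least ``min_area_px`` pixels.  Zero particles is a
    valid result.
    """
    try:
        t = threshold_moments(image)
    except ValueError:
        return []
    binary = image.pixels > t
    labels, n = ndi.label(binary)
    if n == 0:
        return []
    ids = np.arange(1, n + 1)
    areas = ndi.sum_labels(np.ones_like(labels), labels, ids)
    coms = ndi.center_of_mass(binary, labels, ids)
    means = ndi.mean(image.pixels, labels, ids)
    records = []
    pid = 0
    for i, area in enumerate(areas):
        if area < min_area_px:
            continue
        pid += 1
        cy, cx = coms[i]
        records.append(AdhesionRecord(
            particle_id=pid, area_px=int(area),
            area_um2=float(area) * image.pixel_area,
            centroid_um=(float(cx) * image.pixel_size,
                         float(cy) * image.pixel_size),
            mean_intensity=float(means[i]), plane=plane))
    return records


def mean_adhesion_area(records: list[AdhesionRecord]) -> tuple[float, int]:
    """Pooled mean particle area (µm²) and n for one condition."""
    if not records:
        raise ValueError("no adhesion records to average")
    areas = np.array([r.area_um2 for r in records])
    return float(areas.mean()), areas.size


def _take_ranked(candidates: np.ndarray, rank: np.ndarray, n: int) -> np.ndarray:
    """Deterministically keep the n candidate pixels with smallest rank."""
    idx = np.nonzero(candidates.ravel())[0]
    order = np.lexsort((idx, rank.ravel()[idx]))
    keep = idx[order][:n]
    out = np.zeros(candidates.size, dtype=bool)
    out[keep] = True
    return out.reshape(candidates.shape)


def equal_area_regions(nucleus_mask: np.ndarray,
                       region_frac: float = 0.5,
                       exclude: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Equal-area nuclear core and perinuclear band around one nucleus.

    The target area A = round(region_frac * nucleus area).  The nuclear
    region keeps the A innermost nucleus pixels (largest distance to the
    nuclear boundary); the cytoplasmic band keeps the A pixels closest
    outside the nucleus, skipping ``exclude`` (other nuclei) and the
    image border ring.  Raises if the band cannot reach A, reporting the
    achieved area.
    """
    nucleus_mask = nucleus_mask.astype(bool)
    if not nucleus_mask.any():
        raise ValueError("empty nucleus mask")
    area = int(round(region_frac * nucleus_mask.sum()))
    area = max(area, 1)
    edt_in = ndi.distance_transform_edt(nucleus_mask)
    core = _take_ranked(nucleus_mask, -edt_in, area)

    outside = ~nucleus_mask
    if exclude is not None:
        outside &= ~exclude.astype(bool)
    outside[[0, -1], :] = False
    outside[:, [0, -1]] = False
    edt_out = ndi.distance_transform_edt(~nucleus_mask)
    available = int(outside.sum())
    if available < area:
        raise ValueError(
            f"cytoplasmic band reaches only {available} px of the "
            f"required {area} px (border or neighbouring nuclei in the way)")
    band = _take_ranked(outside, edt_out, area)
    return core, band


def yap_nc_ratio(image: RasterImage, nucleus_mask: np.ndarray,
                 region_frac: float = 0.5,
                 exclude: np.ndarray | None = None,
                 cell_id: str = "") -> YapRatioRecord:
    """Nuclear/cytoplasmic mean-intensity ratio over equal-area regions."""
    core, band = equal_area_regions(nucleus_mask, region_frac, exclude)
    nuc = float(image.pixels[core].mean())
    cyt = float(image.pixels[band].mean())
    if cyt == 0:
        raise ValueError("cytoplasmic mean is zero; ratio undefined")
    return YapRatioRecord(cell_id=cell_id, nuclear_mean=nuc,
                          cytoplasmic_mean=cyt, ratio=nuc / cyt,
                          region_area_px=int(core.sum()))


def adhesion_records_to_frame(records: list[AdhesionRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "particle_id": r.particle_id, "area_px": r.area_px,
        "area_um2": r.area_um2, "centroid_x_um": r.centroid_um[0],
        "centroid_y_um": r.centroid_um[1],
        "mean_intensity": r.mean_intensity, "plane": r.plane,
    } for r in records])
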