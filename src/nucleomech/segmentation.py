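"""Nucleus and lamina segmentation with histogram auto-thresholds.

The nuclear pipeline mirrors the classic interactive-macro recipe:
Gaussian filter on the DAPI channel, iso-data ("Default") auto-threshold,
hole filling, distance-transform watershed to split touching nuclei, and
size/border filtering.  The lamina is detected on the lamin channel as
the intersection of two moment-preserving (Tsai) thresholdings — one of
the raw image and one of a top-hat + Gaussian filtered copy — then split
by watershed and assigned to nuclei by pixel overlap.

Both thresholds are defined on a 256-bin histogram stretched over the
image min–max, which reproduces 8-bit-style behavior on data of any bit
depth and makes the returned threshold shift-equivariant.  Foreground is
always "strictly above threshold" (dark background polarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian
from skimage.morphology import disk, white_tophat, opening, erosion, h_maxima
from skimage.segmentation import watershed, clear_border

from .images import RasterImage, ImageStack, LabelMask

__all__ = [
    "NucleusRecord",
    "SegmentationConfig",
    "LaminaConfig",
    "histogram_256",
    "threshold_isodata",
    "threshold_moments",
    "segment_nuclei",
    "detect_lamina",
    "split_and_assign_laminae",
    "measure_intensities",
]

N_BINS = 256


@dataclass
class NucleusRecord:
    """One segmented nucleus, its assigned lamina and measurements."""

    nucleus_id: int
    nucleus_mask: np.ndarray
    lamina_mask: np.ndarray | None = None
    mean_intensity_nucleus: dict = field(default_factory=dict)  # channel -> a.u.
    mean_intensity_lamina: dict = field(default_factory=dict)
    descriptors: object | None = None  # filled by the morphometry stage
    pixel_size: float = 1.0


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of the nuclear segmentation pipeline (defaults as documented)."""

    gaussian_sigma: float = 2.0    # px, DAPI pre-filter
    min_area_um2: float = 10.0     # discard smaller objects
    remove_border: bool = True
    h_maxima: float = 4.0          # px, seed suppression depth for watershed


@dataclass(frozen=True)
class LaminaConfig:
    morphology_op: str = "tophat"   # or "opening"/"erosion"
    morphology_radius: int = 4      # px, circular structuring element
    gaussian_sigma: float = 1.0     # px, after the morphology filter


def histogram_256(pixels: np.ndarray) -> tuple[np.ndarray, float, float]:
    """256-bin histogram over [min, max]; returns (counts, lo, width).

    Bin i covers [lo + i*width, lo + (i+1)*width); intensity of bin
    center i is lo + (i + 0.5) * width.
    """
    px = np.asarray(pixels, dtype=np.float64).ravel()
    lo, hi = float(px.min()), float(px.max())
    if hi <= lo:
        raise ValueError("degenerate histogram: image is constant")
    width = (hi - lo) / N_BINS
    idx = np.minimum(((px - lo) / width).astype(np.int64), N_BINS - 1)
    counts = np.bincount(idx, minlength=N_BINS).astype(np.float64)
    return counts, lo, width


def _bin_to_intensity(bin_value: float, lo: float, width: float) -> float:
    # bin_value is in bin-center units
    return lo + (bin_value + 0.5) * width


def threshold_isodata(image: RasterImage | np.ndarray,
                      clip_ends: bool = False) -> float:
    """Iso-data (intermeans) auto-threshold, iterative "Default" variant.

    Scans cut positions from the low end of the occupied histogram range
    and stops at the fixed point of t = (mean below t + mean above t)/2;
    the returned value is that intermeans level mapped back to intensity
    units (foreground = strictly above it).  ``clip_ends`` zeroes the two
    extreme bins first, the original tool's workaround for saturated or
    erased pixels; off by default because it discards genuine two-level
    histograms.
    """
    px = image.pixels if isinstance(image, RasterImage) else np.asarray(image)
    counts, lo, width = histogram_256(px)
    h = counts.copy()
    if clip_ends:
        h[0] = 0.0
        h[-1] = 0.0
        if h.sum() == 0:
            raise ValueError("degenerate histogram after end-bin clipping")
    nz = np.nonzero(h)[0]
    mn, mx = int(nz[0]), int(nz[-1])
    if mn >= mx:
        raise ValueError("degenerate histogram: single occupied bin")
    i = np.arange(N_BINS, dtype=np.float64)
    csum = np.cumsum(h)
    cmoment = np.cumsum(i * h)
    moving = mn
    while True:
        below_n, below_m = csum[moving], cmoment[moving]
        above_n = csum[mx] - below_n
        above_m = cmoment[mx] - below_m
        result = 0.5 * (below_m / below_n + above_m / above_n)
        moving += 1
        if not (moving + 1 <= result and moving < mx - 1):
            break
    return _bin_to_intensity(result, lo, width)


def _tsai_p0(counts: np.ndarray) -> float:
    """Below-threshold mass p0 preserving the first three gray moments."""
    p = counts / counts.sum()
    i = np.arange(N_BINS, dtype=np.float64)
    m1 = float(p @ i)
    m2 = float(p @ i ** 2)
    m3 = float(p @ i ** 3)
    cd = m2 - m1 * m1
    if cd <= 0:
        raise ValueError("degenerate histogram: zero variance")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        raise ValueError("moment system has no real two-level solution")
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    return float((z1 - m1) / (z1 - z0))


def threshold_moments(image: RasterImage | np.ndarray) -> float:
    """Tsai moment-preserving auto-threshold on a 256-bin histogram.

    Solves for the two-level image preserving the first three gray-level
    moments; the threshold is the upper edge of the first histogram bin
    whose cumulative mass reaches the below-level fraction p0.
    Foreground = strictly above the returned intensity.
    """
    px = image.pixels if isinstance(image, RasterImage) else np.asarray(image)
    counts, lo, width = histogram_256(px)
    p0 = _tsai_p0(counts)
    cum = np.cumsum(counts / counts.sum())
    t_bin = int(np.searchsorted(cum, p0))  # first bin with cum >= p0
    t_bin = min(t_bin, N_BINS - 1)
    return lo + (t_bin + 1) * width  # upper edge of the chosen bin


def segment_nuclei(dapi: RasterImage,
                   cfg: SegmentationConfig | None = None) -> LabelMask:
    """Segment nucleus instances from a DAPI image.

    Gaussian filter -> iso-data threshold -> fill holes -> distance
    watershed (h-maxima seeded) -> drop objects below the minimum area
    and, by default, objects touching the border.  Returns instance
    labels (possibly empty: zero nuclei is a warning-free valid result).
    """
    cfg = cfg or SegmentationConfig()
    sm = gaussian(dapi.pixels, sigma=cfg.gaussian_sigma, preserve_range=True)
    try:
        t = threshold_isodata(sm)
    except ValueError:
        return LabelMask(np.zeros(dapi.shape, np.int32), dapi.pixel_size,
                         "segment_nuclei")
    binary = ndi.binary_fill_holes(sm > t)
    if not binary.any():
        return LabelMask(np.zeros(dapi.shape, np.int32), dapi.pixel_size,
                         "segment_nuclei")
    labels = _distance_watershed(binary, cfg.h_maxima)
    min_px = cfg.min_area_um2 / dapi.pixel_area
    labels = _filter_objects(labels, min_px, cfg.remove_border)
    return LabelMask(labels, dapi.pixel_size, "segment_nuclei")


def _distance_watershed(binary: np.ndarray, h: float) -> np.ndarray:
    dist = ndi.distance_transform_edt(binary)
    # light smoothing removes ridge wiggles from boundary pixelation that
    # would otherwise seed spurious splits
    dist = ndi.gaussian_filter(dist, 1.0)
    seeds_mask = h_maxima(dist, h) if h > 0 else dist == ndi.maximum_filter(dist, 3)
    seeds, n = ndi.label(seeds_mask)
    if n == 0:
        lab, _ = ndi.label(binary)
        return lab
    return watershed(-dist, seeds, mask=binary)


def _filter_objects(labels: np.ndarray, min_px: float,
                    remove_border: bool) -> np.ndarray:
    if remove_border:
        labels = clear_border(labels)
    out = np.zeros_like(labels)
    next_id = 0
    for lab in np.unique(labels):
        if lab == 0:
            continue
        m = labels == lab
        if m.sum() >= min_px:
            next_id += 1
            out[m] = next_id
    return out


def detect_lamina(lamin: RasterImage,
                  cfg: LaminaConfig | None = None) -> np.ndarray:
    """Detect the lamina as raw-threshold AND filtered-threshold overlap.

    The filtered route applies a circular gray-morphology filter (white
    top-hat by default, which isolates the thin bright rim) followed by a
    Gaussian, then the same moment-preserving threshold; the returned
    binary mask is the intersection of the two foregrounds.
    """
    cfg = cfg or LaminaConfig()
    raw = lamin.pixels
    se = disk(cfg.morphology_radius)
    if cfg.morphology_op == "tophat":
        filt = white_tophat(raw, se)
    elif cfg.morphology_op == "opening":
        filt = opening(raw, se)
    elif cfg.morphology_op == "erosion":
        filt = erosion(raw, se)
    else:
        raise ValueError(f"unknown morphology op '{cfg.morphology_op}'")
    filt = gaussian(filt, sigma=cfg.gaussian_sigma, preserve_range=True)
    mask_raw = raw > threshold_moments(raw)
    mask_filt = filt > threshold_moments(filt)
    return mask_raw & mask_filt


def split_and_assign_laminae(lamina_mask: np.ndarray, nuclei: LabelMask,
                             h: float = 2.0):
    """Watershed-split the lamina and assign pieces to nuclei by overlap.

    Each lamina component goes to the nucleus with which it shares the
    most pixels (>= 1 px required; ties broken toward the lower nucleus
    label).  Returns (assignment dict nucleus_id -> lamina mask,
    unassigned component mask).
    """
    if lamina_mask.shape != nuclei.labels.shape:
        raise ValueError("lamina mask and nucleus labels differ in shape")
    pieces = _distance_watershed(lamina_mask.astype(bool), h)
    assigned: dict[int, np.ndarray] = {}
    unassigned = np.zeros_like(lamina_mask, dtype=bool)
    for lab in np.unique(pieces):
        if lab == 0:
            continue
        comp = pieces == lab
        overlaps = nuclei.labels[comp]
        overlaps = overlaps[overlaps > 0]
        if overlaps.size == 0:
            unassigned |= comp
            continue
        ids, counts = np.unique(overlaps, return_counts=True)
        best = int(ids[np.lexsort((ids, -counts))][0])
        if best in assigned:
            assigned[best] = assigned[best] | comp
        else:
            assigned[best] = comp
    return assigned, unassigned


def measure_intensities(nuclei: LabelMask,
                        lamina_by_nucleus: dict[int, np.ndarray],
                        stack: ImageStack,
                        channels: list[str] | None = None,
                        z: int = 0,
                        background: float = 0.0) -> list[NucleusRecord]:
    """Mean intensity per nucleus region and per assigned lamina region.

    ``background`` is subtracted from every mean when nonzero (off by
    default).  Empty masks yield a missing (NaN) intensity, never zero.
    """
    channels = list(channels) if channels is not None \
        else list(stack.channel_names)
    records = []
    for nid in nuclei.ids:
        nmask = nuclei.region(int(nid))
        lmask = lamina_by_nucleus.get(int(nid))
        rec = NucleusRecord(int(nid), nmask, lmask,
                            pixel_size=nuclei.pixel_size)
        for ch in channels:
            plane = stack.plane(z, ch).pixels
            rec.mean_intensity_nucleus[ch] = (
                float(plane[nmask].mean() - background) if nmask.any()
                else float("nan"))
            rec.mean_intensity_lamina[ch] = (
                float(plane[lmask].mean() - background)
                if lmask is not None and lmask.any() else float("nan"))
        records.append(rec)
    return records


def records_to_frame(records: list[NucleusRecord]) -> pd.DataFrame:
    """Flatten records to one row per nucleus for CSV export."""
    rows = []
    for r in records:
        row = {"nucleus_id": r.nucleus_id,
               "area_um2": float(r.nucleus_mask.sum()) * r.pixel_size ** 2,
               "has_lamina": r.lamina_mask is not None}
        for ch, v in r.mean_intensity_nucleus.items():
            row[f"mean_nucleus_{ch}"] = v
        for ch, v in r.mean_intensity_lamina.items():
            row[f"mean_lamina_{ch}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
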