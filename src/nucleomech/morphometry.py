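"""Nuclear shape descriptors and deformed/normal classification.

Descriptors follow the common high-content conventions: the fitted
ellipse comes from second-order image moments, roundness is
4*area/(pi*major_axis^2) (1 for a circle), the axial length ratio is
minor/major of the fitted ellipse, and the width-to-length ratio is the
axis-aligned bounding-box aspect.  The lamin fragmentation index — an
operational reconstruction of a proprietary invagination score — counts
connected lamin fragments that intrude into the nuclear interior:
lamin signal inside the convex hull of the nucleus eroded by a
peripheral band of the lamina's own width.  A smooth nucleus whose
lamina is a single closed peripheral ring scores 0; each envelope
infolding contributes a fragment.

The deformed/normal rule is not a published criterion; it is a
config-driven disjunction (fragmentation, low roundness, or low
solidity) whose thresholds are embedded in every report.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops
from skimage.morphology import convex_hull_image, erosion, disk

from .segmentation import NucleusRecord

__all__ = [
    "ShapeDescriptors",
    "DeformationRule",
    "DeformationReport",
    "compute_descriptors",
    "fragmentation_index",
    "classify_deformed",
    "summarize_condition",
]

MIN_RELIABLE_PX = 9


@dataclass
class ShapeDescriptors:
    area: float                  # µm²
    perimeter: float             # µm
    major_axis: float            # µm, fitted-ellipse full axis
    minor_axis: float            # µm
    roundness: float             # 4*area / (pi * major^2)
    width_to_length: float       # bounding-box short/long side
    axial_length_ratio: float    # minor/major of the fitted ellipse
    solidity: float              # area / convex hull area
    fragmentation_index: int | None = None
    deformed: bool | None = None
    reliable: bool = True


@dataclass(frozen=True)
class DeformationRule:
    """Deformed iff any clause fires; thresholds are reported verbatim."""

    fi_min: float = 1.0          # fragmentation_index >= fi_min
    roundness_max: float = 0.6   # roundness < roundness_max
    solidity_max: float = 0.92   # solidity < solidity_max

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class DeformationReport:
    condition: str
    n_nuclei: int
    n_excluded: int
    percent_deformed: float
    descriptor_stats: pd.DataFrame   # mean ± SD per descriptor
    rule: dict


def compute_descriptors(nucleus: NucleusRecord | np.ndarray,
                        pixel_size: float | None = None) -> ShapeDescriptors:
    """Shape descriptors of one nucleus mask.

    Accepts a :class:`NucleusRecord` or a boolean mask plus pixel size.
    Masks under 9 px are measured anyway but flagged unreliable.
    """
    if isinstance(nucleus, NucleusRecord):
        mask = nucleus.nucleus_mask
        pixel_size = pixel_size if pixel_size is not None else nucleus.pixel_size
    else:
        mask = np.asarray(nucleus, dtype=bool)
        pixel_size = 1.0 if pixel_size is None else pixel_size
    if not mask.any():
        raise ValueError("empty nucleus mask")
    props = regionprops(mask.astype(np.uint8))[0]
    area_px = props.area
    major_px = props.axis_major_length
    minor_px = props.axis_minor_length
    rows = np.any(mask, axis=1).sum()
    cols = np.any(mask, axis=0).sum()
    length, width = (max(rows, cols), min(rows, cols))
    roundness = 4.0 * area_px / (np.pi * major_px ** 2) if major_px > 0 else 1.0
    return ShapeDescriptors(
        area=float(area_px) * pixel_size ** 2,
        perimeter=float(props.perimeter) * pixel_size,
        major_axis=float(major_px) * pixel_size,
        minor_axis=float(minor_px) * pixel_size,
        roundness=float(roundness),
        width_to_length=float(width / length),
        axial_length_ratio=float(minor_px / major_px) if major_px > 0 else 1.0,
        solidity=float(props.solidity),
        reliable=area_px >= MIN_RELIABLE_PX,
    )


def estimate_ring_width(lamina_mask: np.ndarray) -> float:
    """Median width (px) of a ribbon-like mask via its distance transform."""
    if not lamina_mask.any():
        return 0.0
    edt = ndi.distance_transform_edt(lamina_mask)
    # a ribbon of width w has interior distances up to w/2
    return float(2.0 * np.percentile(edt[lamina_mask], 75))


def fragmentation_index(nucleus_mask: np.ndarray,
                        lamina_mask: np.ndarray | None,
                        band_width: float | None = None,
                        min_fragment_px: int = 4) -> int | None:
    """Count lamin fragments intruding into the nuclear interior.

    The interior reference is the convex hull of the nucleus eroded by
    ``band_width`` pixels (default: the lamina's own median ring width
    plus a 2 px discretization margin) — invaginations are intrusions
    from the envelope
    into the convex interior, so a peripheral ring never counts while
    each infolding contributes one connected fragment.  Returns None
    when no lamina is assigned.
    """
    if lamina_mask is None or not lamina_mask.any():
        return None
    if band_width is None:
        band_width = max(estimate_ring_width(lamina_mask) + 2.0, 3.0)
    hull = convex_hull_image(nucleus_mask)
    interior = erosion(hull, disk(int(np.ceil(band_width))))
    inner = lamina_mask & interior
    if not inner.any():
        return 0
    labels, n = ndi.label(inner)
    sizes = ndi.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    return int(np.count_nonzero(sizes >= min_fragment_px))


def classify_deformed(desc: ShapeDescriptors,
                      rule: DeformationRule | None = None) -> bool:
    """Apply the deformed/normal rule; missing FI falls back to shape only."""
    rule = rule or DeformationRule()
    clauses = [desc.roundness < rule.roundness_max,
               desc.solidity < rule.solidity_max]
    if desc.fragmentation_index is not None:
        clauses.append(desc.fragmentation_index >= rule.fi_min)
    deformed = bool(any(clauses))
    desc.deformed = deformed
    return deformed


_NUMERIC_FIELDS = ["area", "perimeter", "major_axis", "minor_axis",
                   "roundness", "width_to_length", "axial_length_ratio",
                   "solidity"]


def summarize_condition(descriptors: list[ShapeDescriptors],
                        condition: str,
                        rule: DeformationRule | None = None,
                        ) -> DeformationReport:
    """Percent deformed and mean ± SD of each descriptor for one condition.

    Unreliable (tiny-mask) nuclei are excluded and counted; nuclei whose
    ``deformed`` flag is unset are classified here with ``rule``.  A
    single-nucleus condition reports SD as missing (NaN), not 0.
    """
    rule = rule or DeformationRule()
    valid = [d for d in descriptors if d.reliable]
    if not valid:
        raise ValueError("no valid nuclei to summarize")
    for d in valid:
        if d.deformed is None:
            classify_deformed(d, rule)
    n = len(valid)
    n_def = sum(bool(d.deformed) for d in valid)
    stats = []
    for name in _NUMERIC_FIELDS:
        vals = np.array([getattr(d, name) for d in valid], dtype=float)
        stats.append({"descriptor": name,
                      "mean": float(vals.mean()),
                      "sd": float(vals.std(ddof=1)) if n > 1 else np.nan})
    fi = [d.fragmentation_index for d in valid
          if d.fragmentation_index is not None]
    if fi:
        fi = np.asarray(fi, dtype=float)
        stats.append({"descriptor": "fragmentation_index",
                      "mean": float(fi.mean()),
                      "sd": float(fi.std(ddof=1)) if fi.size > 1 else np.nan})
    return DeformationReport(
        condition=condition, n_nuclei=n,
        n_excluded=len(descriptors) - n,
        percent_deformed=100.0 * n_def / n,
        descriptor_stats=pd.DataFrame(stats),
        rule=rule.as_dict(),
    )


def descriptors_to_frame(descs: list[ShapeDescriptors]) -> pd.DataFrame:
    return pd.DataFrame([asdict(d) for d in descs])
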