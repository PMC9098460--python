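"""Synthetic phantoms with pixel/sample-exact ground truth.

Every analysis stage in this package is validated against data generated
here: nuclei with a bright lamina rim and parameterized envelope
invaginations (DAPI + lamin channels), fields of small elliptical
focal-adhesion particles, two-compartment cells with a known
nuclear:cytoplasmic intensity ratio, and Hertzian force-indentation
curves.  Ground truth (masks, truth tables, generating parameters) is
emitted before blur and noise are applied, so it is exact.

Invaginations are modeled as inward circular-segment bites centered at
equally spaced, jittered boundary angles: one depth knob produces
lamin-positive infoldings without changing topology (the nucleus stays
simply connected for depths below 0.8 of the minor semi-axis).

All generators are pure functions of (spec, seed): identical inputs give
bit-identical outputs.  Noise is additive Gaussian; photon (Poisson)
statistics are deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import disk, erosion

from .afm import hertz_force, ForceCurve
from .images import RasterImage, ImageStack, LabelMask

__all__ = [
    "SyntheticNucleusSpec",
    "SyntheticAdhesionFieldSpec",
    "SyntheticYapCellSpec",
    "SyntheticCurveSpec",
    "SyntheticScene",
    "nucleus_truth_masks",
    "render_nucleus_image",
    "render_scene",
    "render_adhesion_image",
    "render_yap_cell",
    "simulate_force_curve",
    "sample_nucleus_cohort",
]


# --------------------------------------------------------------------------
# specs

@dataclass(frozen=True)
class SyntheticNucleusSpec:
    """Geometry and photometry of one synthetic nucleus.

    Lengths in pixels, intensities in arbitrary units.  ``semi_axes``
    is (a, b) with a >= b; ``invagination_depth`` is a fraction of b.
    """

    center: tuple[float, float] = (64.0, 64.0)       # (x, y) px
    semi_axes: tuple[float, float] = (40.0, 30.0)    # (a, b) px, a >= b
    orientation: float = 0.0                          # radians
    n_invaginations: int = 0
    invagination_depth: float = 0.3                   # fraction of b, [0, 0.8]
    invagination_width: float = 0.5                   # radians
    lamina_thickness: float = 3.0                     # px
    lamina_intensity: float = 3000.0
    interior_intensity: float = 1200.0
    background_intensity: float = 100.0
    noise_sd: float = 0.0
    psf_sigma: float = 1.0                            # px

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a > 0 and b > 0):
            raise ValueError("semi-axes must be strictly positive")
        if a < b:
            raise ValueError("semi_axes must satisfy a >= b")
        if not 0 <= self.invagination_depth <= 0.8:
            raise ValueError("invagination_depth must lie in [0, 0.8]")
        if self.n_invaginations < 0:
            raise ValueError("n_invaginations must be >= 0")
        if self.lamina_thickness <= 0:
            raise ValueError("lamina_thickness must be positive")


@dataclass(frozen=True)
class SyntheticAdhesionFieldSpec:
    """A field of disjoint bright elliptical particles on cytoplasm."""

    n_particles: int = 50
    particle_semi_axes_range: tuple[float, float] = (4.0, 10.0)  # px
    particle_intensity: float = 3000.0
    cytoplasm_intensity: float = 500.0
    background_intensity: float = 500.0
    noise_sd: float = 30.0
    psf_sigma: float = 1.0
    image_shape: tuple[int, int] = (512, 512)
    min_gap: float = 3.0          # px clearance between particles
    max_attempts: int = 10000

    def __post_init__(self) -> None:
        lo, hi = self.particle_semi_axes_range
        if not 0 < lo <= hi:
            raise ValueError("particle semi-axis range must be 0 < min <= max")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")


@dataclass(frozen=True)
class SyntheticYapCellSpec:
    """Two-compartment cell: nucleus inside cytoplasm, background zero."""

    nucleus: SyntheticNucleusSpec = field(
        default_factory=lambda: SyntheticNucleusSpec(
            center=(128.0, 128.0), semi_axes=(30.0, 22.0)))
    cell_semi_axes: tuple[float, float] = (90.0, 70.0)   # px
    nuclear_mean: float = 200.0
    cytoplasm_mean: float = 100.0
    noise_sd: float = 0.0
    image_shape: tuple[int, int] = (256, 256)
    clearance: float = 12.0       # px, min cytoplasm ring around the nucleus

    @property
    def true_ratio(self) -> float:
        return self.nuclear_mean / self.cytoplasm_mean


@dataclass(frozen=True)
class SyntheticCurveSpec:
    """A Hertzian indentation curve with baseline, contact shift and noise.

    The recorded depth axis spans [-pre_contact, delta_max]; true contact
    occurs at ``contact_shift`` on that axis, so the noiseless force is
    ``baseline_offset`` for depths <= contact_shift and follows the Hertz
    form in (depth - contact_shift) beyond it.  As on the instrument, the
    ramp stops once the indentation force reaches ``force_stop`` (2 nN by
    default), so samples whose noiseless force exceeds it are not
    recorded.
    """

    E_true: float = 1000.0        # Pa
    nu: float = 0.5
    R: float = 5e-6               # m (10 µm bead)
    delta_max: float = 1.0e-6     # m, end of the recorded axis
    n_points: int = 600
    baseline_offset: float = 0.0  # N
    contact_shift: float = 0.2e-6  # m
    pre_contact: float = 0.5e-6   # m of pre-contact travel recorded
    force_stop: float = 2e-9      # N, acquisition force threshold
    noise_sd: float = 0.0         # N
    seed: int = 0

    def __post_init__(self) -> None:
        if self.E_true <= 0 or self.R <= 0:
            raise ValueError("E_true and R must be positive")
        if not 0 < self.nu <= 0.5:
            raise ValueError("Poisson's ratio must be in (0, 0.5]")
        if self.contact_shift < 0 or self.delta_max <= self.contact_shift:
            raise ValueError("need 0 <= contact_shift < delta_max")
        if self.n_points < 4:
            raise ValueError("n_points too small")


@dataclass(frozen=True)
class SyntheticScene:
    """Rendered image(s) plus exact ground truth for one synthetic field."""

    image: ImageStack
    nucleus_labels: LabelMask
    lamina_mask: np.ndarray
    truth: pd.DataFrame
    seed: int


# --------------------------------------------------------------------------
# geometry helpers

def _ellipse_mask(shape, center, semi_axes, orientation) -> np.ndarray:
    h, w = shape
    cx, cy = center
    a, b = semi_axes
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    c, s = np.cos(orientation), np.sin(orientation)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _disk_mask(shape, center, radius) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius ** 2


def nucleus_truth_masks(spec: SyntheticNucleusSpec, shape: tuple[int, int],
                        rng: np.random.Generator | None = None,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the analytic nucleus region and its lamina rim, pre-blur.

    The region is the ellipse minus inward circular-segment bites; the
    rim is the region minus its erosion by a disk of the lamina
    thickness, i.e. a band of that width tracing the (invaginated)
    boundary.  Invagination angles are equally spaced with jitter drawn
    from ``rng`` (no jitter when rng is None).
    """
    a, b = spec.semi_axes
    cx, cy = spec.center
    mask = _ellipse_mask(shape, spec.center, spec.semi_axes, spec.orientation)
    k = spec.n_invaginations
    if k > 0 and spec.invagination_depth > 0:
        base = np.linspace(0, 2 * np.pi, k, endpoint=False)
        jitter = rng.uniform(-0.3, 0.3, size=k) if rng is not None else 0.0
        phis = base + jitter + (rng.uniform(0, 2 * np.pi) if rng is not None else 0.0)
        d = spec.invagination_depth * b
        half_chord = max(0.5 * spec.invagination_width * b, 1.5)
        r_bite = (half_chord ** 2 + d ** 2) / (2.0 * d)
        co, so = np.cos(spec.orientation), np.sin(spec.orientation)
        for phi in np.atleast_1d(phis):
            # boundary point and outward normal, in image coordinates
            px_, py_ = a * np.cos(phi), b * np.sin(phi)
            nx_, ny_ = np.cos(phi) / a, np.sin(phi) / b
            nn = np.hypot(nx_, ny_)
            nx_, ny_ = nx_ / nn, ny_ / nn
            bx = cx + px_ * co - py_ * so
            by = cy + px_ * so + py_ * co
            ox = nx_ * co - ny_ * so
            oy = nx_ * so + ny_ * co
            centerb = (bx + ox * (r_bite - d), by + oy * (r_bite - d))
            mask &= ~_disk_mask(shape, centerb, r_bite)
    rim = mask & ~erosion(mask, disk(int(round(spec.lamina_thickness))))
    return mask, rim


def _render_channels(shape, nucleus_mask, rim_mask, spec, rng):
    dapi = np.full(shape, spec.background_intensity, dtype=np.float64)
    dapi[nucleus_mask] = spec.interior_intensity
    lamin = np.full(shape, spec.background_intensity, dtype=np.float64)
    lamin[rim_mask] = spec.lamina_intensity
    if spec.psf_sigma > 0:
        dapi = ndi.gaussian_filter(dapi, spec.psf_sigma)
        lamin = ndi.gaussian_filter(lamin, spec.psf_sigma)
    if spec.noise_sd > 0:
        dapi = dapi + rng.normal(0.0, spec.noise_sd, shape)
        lamin = lamin + rng.normal(0.0, spec.noise_sd, shape)
    return dapi, lamin


def _check_inside(mask: np.ndarray, margin: int, what: str) -> None:
    if margin > 0:
        core = np.zeros_like(mask)
        core[margin:-margin or None, margin:-margin or None] = \
            mask[margin:-margin or None, margin:-margin or None]
        clipped = mask & ~core
    else:
        border = np.zeros_like(mask)
        border[[0, -1], :] = True
        border[:, [0, -1]] = True
        clipped = mask & border
    if clipped.any():
        raise ValueError(f"{what} clipped by the image border "
                         f"(needs {margin} px margin)")


def render_nucleus_image(spec: SyntheticNucleusSpec, shape: tuple[int, int],
                         seed: int, pixel_size: float = 0.2) -> SyntheticScene:
    """Render one nucleus as a DAPI+lamin stack with exact truth masks."""
    rng = np.random.default_rng(seed)
    mask, rim = nucleus_truth_masks(spec, shape, rng)
    _check_inside(mask, int(np.ceil(3 * spec.psf_sigma)) + 1, "nucleus")
    dapi, lamin = _render_channels(shape, mask, rim, spec, rng)
    stack = ImageStack(np.stack([dapi, lamin])[None], ("dapi", "lamin"),
                       pixel_size)
    labels = LabelMask(mask.astype(np.int32), pixel_size, "synthetic truth")
    truth = pd.DataFrame([{
        "nucleus_id": 1, "center_x": spec.center[0], "center_y": spec.center[1],
        "semi_a": spec.semi_axes[0], "semi_b": spec.semi_axes[1],
        "n_invaginations": spec.n_invaginations,
        "invagination_depth": spec.invagination_depth,
        "area_px": int(mask.sum()),
    }])
    return SyntheticScene(stack, labels, rim, truth, seed)


def render_scene(n_nuclei: int, shape: tuple[int, int] = (512, 512),
                 seed: int = 0, pixel_size: float = 0.2,
                 base_spec: SyntheticNucleusSpec | None = None,
                 axis_range: tuple[float, float] = (22.0, 42.0),
                 deformed_fraction: float = 0.0,
                 min_gap: float = 4.0,
                 max_attempts: int = 5000) -> SyntheticScene:
    """Render a field of non-overlapping nuclei with instance ground truth.

    Nuclei are placed by rejection sampling with at least ``min_gap``
    pixels of clearance between regions; a fraction of them can carry
    invaginations (3 bites at the base spec's depth) for deformation
    cohorts.
    """
    rng = np.random.default_rng(seed)
    base = base_spec or SyntheticNucleusSpec()
    h, w = shape
    margin = int(np.ceil(3 * base.psf_sigma)) + 2
    labels = np.zeros(shape, dtype=np.int32)
    rim_all = np.zeros(shape, dtype=bool)
    occupied = np.zeros(shape, dtype=bool)
    gap = disk(int(round(min_gap)))
    rows = []
    placed = 0
    attempts = 0
    while placed < n_nuclei:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n_nuclei} nuclei in {shape} after "
                f"{max_attempts} attempts: field too dense")
        b = rng.uniform(*axis_range)
        a = b * rng.uniform(1.0, 1.5)
        theta = rng.uniform(0, np.pi)
        reach = a + margin
        cx = rng.uniform(reach, w - reach)
        cy = rng.uniform(reach, h - reach)
        deformed = rng.random() < deformed_fraction
        spec = replace(base, center=(cx, cy), semi_axes=(a, b),
                       orientation=theta,
                       n_invaginations=3 if deformed else 0)
        mask, rim = nucleus_truth_masks(spec, shape, rng)
        if (ndi.binary_dilation(mask, gap) & occupied).any():
            continue
        placed += 1
        labels[mask] = placed
        rim_all |= rim
        occupied |= mask
        rows.append({
            "nucleus_id": placed, "center_x": cx, "center_y": cy,
            "semi_a": a, "semi_b": b, "orientation": theta,
            "n_invaginations": spec.n_invaginations,
            "deformed_true": bool(deformed),
            "area_px": int(mask.sum()),
        })
    dapi, lamin = _render_channels(shape, labels > 0, rim_all, base, rng)
    stack = ImageStack(np.stack([dapi, lamin])[None], ("dapi", "lamin"),
                       pixel_size)
    truth = pd.DataFrame(rows, columns=[
        "nucleus_id", "center_x", "center_y", "semi_a", "semi_b",
        "orientation", "n_invaginations", "deformed_true", "area_px"])
    return SyntheticScene(stack, LabelMask(labels, pixel_size, "synthetic truth"),
                          rim_all, truth, seed)


def render_adhesion_image(spec: SyntheticAdhesionFieldSpec, seed: int,
                          pixel_size: float = 0.2, n_planes: int = 1,
                          defocus_sigma: float = 3.0):
    """Render a focal-adhesion field; returns (image, truth table).

    With ``n_planes > 1`` an image z-stack is returned in which the
    middle plane is in focus and its neighbours are defocused by an
    extra Gaussian blur, for best-plane selection tests.  The truth
    table records each particle's centroid and exact pre-blur pixel
    area.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.image_shape
    base = np.full((h, w), spec.background_intensity, dtype=np.float64)
    cell = _ellipse_mask((h, w), (w / 2, h / 2), (w * 0.47, h * 0.47), 0.0)
    base[cell] = spec.cytoplasm_intensity
    occupied = np.zeros((h, w), dtype=bool)
    gap = disk(int(round(spec.min_gap)))
    rows = []
    sharp = base.copy()
    placed, attempts = 0, 0
    while placed < spec.n_particles:
        attempts += 1
        if attempts > spec.max_attempts:
            raise RuntimeError(
                f"placed only {placed}/{spec.n_particles} particles after "
                f"{spec.max_attempts} attempts: particle density too high "
                f"for {spec.image_shape}")
        lo, hi = spec.particle_semi_axes_range
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, a)
        theta = rng.uniform(0, np.pi)
        cx = rng.uniform(a + 3, w - a - 3)
        cy = rng.uniform(a + 3, h - a - 3)
        mask = _ellipse_mask((h, w), (cx, cy), (a, b), theta)
        if not cell[mask].all():
            continue
        if (ndi.binary_dilation(mask, gap) & occupied).any():
            continue
        placed += 1
        occupied |= mask
        sharp[mask] = spec.particle_intensity
        rows.append({"particle_id": placed, "centroid_x": cx, "centroid_y": cy,
                     "semi_a": a, "semi_b": b,
                     "area_px": int(mask.sum()),
                     "area_um2": float(mask.sum() * pixel_size ** 2)})
    truth = pd.DataFrame(rows, columns=[
        "particle_id", "centroid_x", "centroid_y", "semi_a", "semi_b",
        "area_px", "area_um2"])

    def _finish(img):
        if spec.psf_sigma > 0:
            img = ndi.gaussian_filter(img, spec.psf_sigma)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        return img

    if n_planes <= 1:
        return RasterImage(_finish(sharp), pixel_size), truth
    focus = n_planes // 2
    planes = []
    for z in range(n_planes):
        img = sharp if z == focus else ndi.gaussian_filter(
            sharp, defocus_sigma * abs(z - focus))
        planes.append(_finish(img))
    stack = ImageStack(np.stack(planes)[:, None], ("vinculin",), pixel_size)
    return stack, truth


def render_yap_cell(spec: SyntheticYapCellSpec, seed: int,
                    pixel_size: float = 0.2):
    """Render a two-compartment cell; returns (image, truth dict).

    Nuclear pixels ~ N(nuclear_mean, noise_sd), cytoplasmic pixels ~
    N(cytoplasm_mean, noise_sd), background exactly 0.  Truth carries
    the generating ratio and both masks.
    """
    rng = np.random.default_rng(seed)
    shape = spec.image_shape
    nuc = spec.nucleus
    cell = _ellipse_mask(shape, nuc.center, spec.cell_semi_axes, 0.0)
    nmask, _ = nucleus_truth_masks(nuc, shape, rng)
    shrunk = erosion(cell, disk(int(round(spec.clearance))))
    if not nmask[~shrunk].sum() == 0:
        raise ValueError(
            f"nucleus violates the {spec.clearance} px clearance to the "
            "cell boundary")
    img = np.zeros(shape, dtype=np.float64)
    img[cell] = spec.cytoplasm_mean
    img[nmask] = spec.nuclear_mean
    if spec.noise_sd > 0:
        img = img + np.where(cell, rng.normal(0.0, spec.noise_sd, shape), 0.0)
    truth = {"ratio": spec.true_ratio, "nucleus_mask": nmask,
             "cell_mask": cell, "nuclear_mean": spec.nuclear_mean,
             "cytoplasm_mean": spec.cytoplasm_mean}
    return RasterImage(img, pixel_size), truth


def simulate_force_curve(spec: SyntheticCurveSpec, cell_id: str = "",
                         condition: str = "") -> ForceCurve:
    """Simulate one Hertzian indentation curve per the spec's parameters.

    The noiseless curve is exactly ``baseline_offset`` before contact and
    exactly the Hertz forward model beyond it; Gaussian noise of SD
    ``noise_sd`` (N) is then added sample-wise.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.linspace(-spec.pre_contact, spec.delta_max, spec.n_points)
    f = spec.baseline_offset + hertz_force(x - spec.contact_shift,
                                           spec.E_true, spec.nu, spec.R)
    if spec.force_stop is not None:
        keep = (f - spec.baseline_offset) <= spec.force_stop
        x, f = x[keep], f[keep]
    if spec.noise_sd > 0:
        f = f + rng.normal(0.0, spec.noise_sd, f.shape)
    return ForceCurve(x, f, cell_id=cell_id, condition=condition)


def sample_nucleus_cohort(n: int, deformed_fraction: float, seed: int,
                          shape: tuple[int, int] = (160, 160),
                          pixel_size: float = 0.2,
                          base_spec: SyntheticNucleusSpec | None = None,
                          ) -> list[dict]:
    """Sample n single-nucleus truth masks, a fraction carrying invaginations.

    Returns dicts with ``nucleus_mask``, ``lamina_mask``,
    ``deformed_true`` and the generating spec — the input for
    morphometry-level cohort studies where segmentation is not under
    test.
    """
    rng = np.random.default_rng(seed)
    base = base_spec or SyntheticNucleusSpec(
        center=(shape[1] / 2, shape[0] / 2), semi_axes=(36.0, 28.0),
        invagination_depth=0.35, invagination_width=0.6)
    out = []
    for i in range(n):
        b = rng.uniform(24.0, 32.0)
        a = b * rng.uniform(1.0, 1.5)
        deformed = rng.random() < deformed_fraction
        spec = replace(base, semi_axes=(a, b),
                       orientation=rng.uniform(0, np.pi),
                       n_invaginations=int(rng.integers(2, 5)) if deformed else 0)
        mask, rim = nucleus_truth_masks(spec, shape, rng)
        out.append({"nucleus_mask": mask, "lamina_mask": rim,
                    "deformed_true": bool(deformed), "spec": spec,
                    "pixel_size": pixel_size})
    return out
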