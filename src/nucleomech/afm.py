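"""Hertz spherical-indentation analysis of AFM force curves.

The forward model for a rigid sphere of radius R indenting an elastic
half-space of Young's modulus E and Poisson's ratio nu to depth delta is

    F = (4/3) * E / (1 - nu**2) * sqrt(R * delta**3)

Cells are treated as incompressible (nu = 0.5) by default, probed with a
10 um bead (R = 5 um), and only the shallow part of each curve is fitted
(depth <= 0.5 um, force <= 2 nN) to keep deformations small and suppress
substrate contributions.  The contact point and baseline are estimated
from the pre-contact segment, then E (and optionally the contact point,
within a narrow window) is refined by nonlinear least squares.

All quantities are SI internally (m, N, Pa); readers convert from the
µm/nN conventions common in exported curves.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ForceCurve",
    "HertzFitResult",
    "ContactPointConfig",
    "HertzFitConfig",
    "hertz_force",
    "find_contact_point",
    "fit_hertz",
    "summarize_moduli",
    "read_force_curve",
]

DEFAULT_SPRING_CONSTANT = 0.03  # N/m, soft cantilever for cell indentation
DEFAULT_BEAD_RADIUS = 5e-6      # m, 10 µm sphere
DEFAULT_POISSON = 0.5           # incompressible cell
DEFAULT_DEPTH_GATE = 0.5e-6     # m
DEFAULT_FORCE_GATE = 2e-9       # N


@dataclass(frozen=True)
class ForceCurve:
    """One indentation experiment: depth (m) vs force (N), increasing depth.

    In raw mode construct via :meth:`from_piezo` with piezo height and
    cantilever deflection; then force = k * deflection and
    delta = z - deflection.
    """

    delta: np.ndarray
    force: np.ndarray
    spring_constant: float = DEFAULT_SPRING_CONSTANT
    cell_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.delta, dtype=np.float64)
        f = np.asarray(self.force, dtype=np.float64)
        if d.shape != f.shape or d.ndim != 1:
            raise ValueError("delta and force must be matching 1-D arrays")
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(f))):
            raise ValueError("non-finite samples in force curve")
        if np.any(np.diff(d) <= 0):
            order = np.argsort(d, kind="stable")
            d, f = d[order], f[order]
        object.__setattr__(self, "delta", d)
        object.__setattr__(self, "force", f)

    @classmethod
    def from_piezo(cls, z: np.ndarray, deflection: np.ndarray,
                   spring_constant: float = DEFAULT_SPRING_CONSTANT,
                   **kw) -> "ForceCurve":
        z = np.asarray(z, dtype=np.float64)
        defl = np.asarray(deflection, dtype=np.float64)
        return cls(z - defl, spring_constant * defl,
                   spring_constant=spring_constant, **kw)

    def __len__(self) -> int:
        return self.delta.size

    @property
    def sample_spacing(self) -> float:
        return float(np.median(np.diff(self.delta)))


@dataclass(frozen=True)
class HertzFitResult:
    E: float                 # Pa
    nu: float
    R: float                 # m
    contact_point: float     # m, on the curve's depth axis
    baseline: float          # N
    n_points_used: int
    rss: float               # N^2
    converged: bool
    depth_gate: float        # m
    force_gate: float        # N
    cell_id: str = ""
    condition: str = ""


@dataclass(frozen=True)
class ContactPointConfig:
    baseline_frac: float = 0.2   # fraction of leading samples forming the baseline
    k_sigma: float = 5.0         # detection threshold in robust SDs of the baseline
    refine_window: int = 5       # samples used for linear back-extrapolation
    min_baseline_points: int = 4


@dataclass(frozen=True)
class HertzFitConfig:
    depth_gate: float = DEFAULT_DEPTH_GATE
    force_gate: float = DEFAULT_FORCE_GATE
    min_points: int = 10
    refine_contact: bool = True   # fit delta0 jointly with E
    contact_window: float = 10.0  # forward slack on delta0, in sample spacings
    max_gate_iter: int = 5
    contact: ContactPointConfig = field(default_factory=ContactPointConfig)


def hertz_force(delta, E: float, nu: float = DEFAULT_POISSON,
                R: float = DEFAULT_BEAD_RADIUS):
    """Hertz force (N) at indentation depth(s) ``delta`` (m).

    Negative depths (pre-contact) return 0 by convention.  Vectorized.
    """
    if E <= 0 or R <= 0:
        raise ValueError("E and R must be positive")
    if not 0 <= nu < 1:
        raise ValueError("Poisson's ratio must be in [0, 1)")
    d = np.asarray(delta, dtype=np.float64)
    f = np.zeros_like(d)
    pos = d > 0
    f[pos] = (4.0 / 3.0) * E / (1.0 - nu ** 2) * np.sqrt(R * d[pos] ** 3)
    if np.ndim(delta) == 0:
        return float(f)
    return f


def find_contact_point(curve: ForceCurve,
                       cfg: ContactPointConfig | None = None) -> tuple[float, float]:
    """Estimate (contact point delta0, baseline force) from the pre-rise segment.

    Baseline is the median of the leading ``baseline_frac`` of samples;
    the contact point is the first sample whose force exceeds baseline +
    k_sigma * robust SD, refined by back-extrapolating a local linear fit
    of the rising flank down to the baseline.
    """
    cfg = cfg or ContactPointConfig()
    n = len(curve)
    nb = max(cfg.min_baseline_points, int(round(cfg.baseline_frac * n)))
    if n < nb + 2:
        raise ValueError("curve too short for baseline estimation")
    base_f = curve.force[:nb]
    baseline = float(np.median(base_f))
    mad = float(np.median(np.abs(base_f - baseline)))
    sigma = 1.4826 * mad
    # floor so a noiseless curve still has a usable detection threshold
    span = float(curve.force.max() - baseline)
    thresh = baseline + max(cfg.k_sigma * sigma, 1e-6 * span, 0.0)
    above = np.nonzero(curve.force > thresh)[0]
    above = above[above >= nb - 1] if above.size else above
    if above.size == 0 or span <= 0:
        raise ValueError("no contact detected: curve never rises above baseline")
    i0 = int(above[0])
    # back-extrapolate the rising flank to the baseline level
    j1 = min(n, i0 + cfg.refine_window)
    x, y = curve.delta[i0:j1], curve.force[i0:j1]
    delta0 = float(curve.delta[i0])
    if x.size >= 2:
        slope, intercept = np.polyfit(x, y, 1)
        if slope > 0:
            cross = (baseline - intercept) / slope
            spacing = float(np.median(np.diff(curve.delta)))
            lo = float(curve.delta[i0]) - cfg.refine_window * spacing
            delta0 = float(np.clip(cross, lo, curve.delta[i0]))
    return delta0, baseline


def _gate(curve: ForceCurve, delta0: float, baseline: float,
          cfg: HertzFitConfig) -> np.ndarray:
    d = curve.delta - delta0
    f = curve.force - baseline
    return (d > 0) & (d <= cfg.depth_gate) & (f <= cfg.force_gate)


def _initial_modulus(d: np.ndarray, f: np.ndarray, nu: float, R: float) -> float:
    # linearization: F = c * delta^(3/2); regress through the origin
    x = np.sqrt(np.maximum(d, 0.0) ** 3)
    denom = float(x @ x)
    c = float(x @ f) / denom if denom > 0 else 0.0
    E0 = c * 3.0 * (1.0 - nu ** 2) / (4.0 * np.sqrt(R))
    return max(E0, 1e-12)


def fit_hertz(curve: ForceCurve, R: float = DEFAULT_BEAD_RADIUS,
              nu: float = DEFAULT_POISSON,
              cfg: HertzFitConfig | None = None) -> HertzFitResult:
    """Fit the Hertz model to the gated shallow-indentation part of a curve.

    Points with 0 < delta - delta0 <= depth_gate and
    F - baseline <= force_gate enter an unweighted least-squares fit of E
    (optionally also delta0, bounded to a window of a few sample spacings
    around the detected contact).  The closed-form regression of force on
    depth^(3/2) seeds the optimizer.
    """
    cfg = cfg or HertzFitConfig()
    delta0, baseline = find_contact_point(curve, cfg.contact)
    spacing = abs(curve.sample_spacing)
    window = cfg.contact_window * spacing

    for _ in range(cfg.max_gate_iter):
        sel = _gate(curve, delta0, baseline, cfg)
        n_used = int(sel.sum())
        if n_used < cfg.min_points:
            raise ValueError(
                f"only {n_used} samples inside the depth/force gates "
                f"(need >= {cfg.min_points})")
        d = curve.delta[sel] - delta0
        f = curve.force[sel] - baseline
        E0 = _initial_modulus(d, f, nu, R)
        # nondimensionalize (forces are ~nN, depths ~nm) so the optimizer's
        # tolerances are meaningful: E in units of E0, delta0 offset in
        # sample spacings, residuals in units of the gated force range
        f_scale = max(float(np.abs(f).max()), 1e-300)
        d0_init = delta0

        if cfg.refine_contact:
            # threshold crossing detects contact LATE (the force must clear
            # the noise floor first), so allow delta0 to back up by as much
            # as one depth gate while only a few samples of forward slack
            lo = max(float(curve.delta[0]), delta0 - cfg.depth_gate)
            hi = delta0 + window

            def resid(p):
                e, u = p
                d0c = d0_init + u * spacing
                return (hertz_force(curve.delta[sel] - d0c,
                                    max(e, 1e-12) * E0, nu, R)
                        - (curve.force[sel] - baseline)) / f_scale
            res = least_squares(
                resid, x0=[1.0, 0.0],
                bounds=([1e-12, (lo - d0_init) / spacing],
                        [np.inf, (hi - d0_init) / spacing]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14)
            E_fit = float(res.x[0]) * E0
            d0_fit = d0_init + float(res.x[1]) * spacing
        else:
            def resid(p):
                return (hertz_force(d, max(p[0], 1e-12) * E0, nu, R) - f) \
                    / f_scale
            res = least_squares(resid, x0=[1.0], bounds=([1e-12], [np.inf]),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
            E_fit, d0_fit = float(res.x[0]) * E0, delta0

        new_sel = _gate(curve, d0_fit, baseline, cfg)
        moved = abs(d0_fit - delta0) > 1e-15
        delta0 = d0_fit
        if np.array_equal(new_sel, sel) or not moved:
            sel = new_sel if new_sel.sum() >= cfg.min_points else sel
            break

    sel = _gate(curve, delta0, baseline, cfg)
    if sel.sum() < cfg.min_points:
        raise ValueError("gated sample set collapsed during contact refinement")
    final_resid = hertz_force(curve.delta[sel] - delta0, E_fit, nu, R) \
        - (curve.force[sel] - baseline)
    return HertzFitResult(
        E=E_fit, nu=nu, R=R, contact_point=delta0, baseline=baseline,
        n_points_used=int(sel.sum()), rss=float(final_resid @ final_resid),
        converged=bool(res.success and E_fit > 0),
        depth_gate=cfg.depth_gate, force_gate=cfg.force_gate,
        cell_id=curve.cell_id, condition=curve.condition,
    )


def summarize_moduli(results: list[HertzFitResult],
                     condition: str | None = None) -> pd.DataFrame:
    """Per-condition n, median, quartiles and mean ± SD of E (Pa).

    Non-converged fits are excluded and counted.
    """
    rows = [r for r in results
            if condition is None or r.condition == condition]
    if not rows:
        raise ValueError("no fits to summarize")
    out = []
    for cond in sorted({r.condition for r in rows}):
        sub = [r for r in rows if r.condition == cond]
        conv = [r.E for r in sub if r.converged]
        if not conv:
            raise ValueError(f"zero converged fits for condition '{cond}'")
        e = np.asarray(conv)
        out.append({
            "condition": cond,
            "n": e.size,
            "n_excluded": len(sub) - e.size,
            "median_Pa": float(np.median(e)),
            "q1_Pa": float(np.percentile(e, 25)),
            "q3_Pa": float(np.percentile(e, 75)),
            "mean_Pa": float(e.mean()),
            "sd_Pa": float(e.std(ddof=1)) if e.size > 1 else np.nan,
        })
    return pd.DataFrame(out)


_UNIT_SCALE = {"m": 1.0, "um": 1e-6, "µm": 1e-6, "nm": 1e-9,
               "n": 1.0, "nn": 1e-9, "pn": 1e-12, "un": 1e-6, "µn": 1e-6}


def read_force_curve(path, spring_constant: float | None = None,
                     **kw) -> ForceCurve:
    """Read a delimited-text force curve.

    Two columns = (depth, force); three = (z, deflection, unused) raw mode
    converted with the spring constant (header ``# k = <value> N/m``
    overrides the default).  Units are taken from the header, e.g.
    ``delta_um`` / ``force_nN``; bare names default to SI.
    """
    text = Path(path).read_text()
    k = spring_constant
    m = re.search(r"k\s*=\s*([0-9.eE+-]+)", text)
    if k is None:
        k = float(m.group(1)) if m else DEFAULT_SPRING_CONSTANT
    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("#"))
    df = pd.read_csv(io.StringIO(body), sep=None, engine="python")

    def scale_of(col: str) -> float:
        suffix = col.rsplit("_", 1)[-1].lower()
        return _UNIT_SCALE.get(suffix, 1.0)

    cols = list(df.columns)
    if len(cols) >= 3 and any("defl" in c.lower() for c in cols):
        z = df[cols[0]].to_numpy() * scale_of(cols[0])
        defl = df[cols[1]].to_numpy() * scale_of(cols[1])
        return ForceCurve.from_piezo(z, defl, spring_constant=k, **kw)
    delta = df[cols[0]].to_numpy() * scale_of(cols[0])
    force = df[cols[1]].to_numpy() * scale_of(cols[1])
    return ForceCurve(delta, force, spring_constant=k, **kw)
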