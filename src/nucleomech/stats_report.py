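"""Two-sample comparisons and reproducible run reports.

The between-condition test is the unpaired two-sample t-test, pooled
(classic Student) by default with Welch as an option; both are computed
in closed form and cross-checked against scipy in the test suite.  Run
reports snapshot the config, the seeds and a SHA-256 digest of every
output file so a rerun can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats as sps

__all__ = ["TTestResult", "unpaired_ttest", "benjamini_hochberg",
           "RunReport", "build_report"]


@dataclass(frozen=True)
class TTestResult:
    group_x: str
    group_y: str
    n_x: int
    n_y: int
    mean_x: float
    mean_y: float
    t: float
    df: float
    p: float
    variant: str   # "pooled" or "welch"


def unpaired_ttest(x, y, variant: str = "pooled",
                   labels: tuple[str, str] = ("x", "y")) -> TTestResult:
    """Unpaired two-sample t-test (two-sided).

    ``variant="pooled"`` is the classic equal-variance Student test;
    ``"welch"`` uses the Welch-Satterthwaite correction.  Requires at
    least two finite values per group and non-degenerate variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per group")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite observations")
    nx, ny = x.size, y.size
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if variant == "pooled":
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        if sp2 <= 0:
            raise ValueError("degenerate samples: zero pooled variance")
        se = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
        df = float(nx + ny - 2)
    elif variant == "welch":
        if vx <= 0 and vy <= 0:
            raise ValueError("degenerate samples: zero variance in both groups")
        se = np.sqrt(vx / nx + vy / ny)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    else:
        raise ValueError(f"unknown variant '{variant}'")
    t = (mx - my) / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(labels[0], labels[1], nx, ny, float(mx), float(my),
                       float(t), float(df), min(max(p, np.nextafter(0, 1)), 1.0),
                       variant)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (extension; no correction is applied by default)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


@dataclass
class RunReport:
    config: dict
    seeds: dict
    version: str
    stages: dict   # stage -> {path: digest} or {"status": "absent"}

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def build_report(stage_outputs: dict[str, list], config: dict,
                 seeds: dict, out_dir=None) -> RunReport:
    """Digest every stage's output files into a machine-readable report.

    ``stage_outputs`` maps a stage name to its output file paths; files
    that do not exist are listed as absent rather than failing the
    report.  When ``out_dir`` is given, ``report.json`` and a
    human-readable ``summary.md`` are written there.
    """
    from . import __version__
    stages = {}
    for stage, paths in stage_outputs.items():
        entry = {}
        for p in paths:
            p = Path(p)
            entry[p.name] = _sha256(p) if p.exists() else "absent"
        stages[stage] = entry or {"status": "absent"}
    report = RunReport(config=config, seeds=seeds,
                       version=__version__, stages=stages)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(report.to_json() + "\n")
        lines = ["# Run summary", "",
                 f"package version: {report.version}", "",
                 "| stage | file | sha256 |", "|---|---|---|"]
        for stage, files in stages.items():
            for name, digest in files.items():
                lines.append(f"| {stage} | {name} | {digest[:16]} |")
        (out_dir / "summary.md").write_text("\n".join(lines) + "\n")
    return report
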