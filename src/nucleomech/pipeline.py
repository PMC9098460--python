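"""End-to-end synthetic study: simulate two conditions, quantify, compare.

This driver strings every stage together on synthetic data emulating the
qualitative contrast under study — a control condition with stiff cells,
smooth nuclei, modest focal adhesions and nuclear YAP, versus a
perturbed condition with soft cells, invaginated nuclei, enlarged
adhesions and impaired YAP translocation.  All randomness derives from
one seed; outputs are plain CSV/JSON/TIFF with no timestamps, so two
runs with the same config are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import afm, morphometry, synthetic
from .adhesion_yap import (adhesion_records_to_frame, mean_adhesion_area,
                           segment_adhesions, select_best_plane, yap_nc_ratio)
from .images import write_tiff
from .morphometry import (DeformationRule, classify_deformed,
                          compute_descriptors, descriptors_to_frame,
                          fragmentation_index, summarize_condition)
from .segmentation import (SegmentationConfig, detect_lamina,
                           measure_intensities, records_to_frame,
                           segment_nuclei, split_and_assign_laminae)
from .stats_report import build_report, unpaired_ttest
from .synthetic import (SyntheticAdhesionFieldSpec, SyntheticCurveSpec,
                        SyntheticYapCellSpec, render_adhesion_image,
                        render_scene, render_yap_cell, simulate_force_curve)

__all__ = ["PipelineConfig", "ConditionSpec", "run_pipeline"]


@dataclass(frozen=True)
class ConditionSpec:
    """Generating parameters of one synthetic experimental condition."""

    name: str
    E_kpa: float = 4.0                 # cell stiffness
    deformed_fraction: float = 0.1     # nuclei carrying invaginations
    fa_axes: tuple[float, float] = (4.0, 8.0)   # particle semi-axis range, px
    yap_ratio: float = 2.5             # nuclear/cytoplasmic YAP


@dataclass(frozen=True)
class PipelineConfig:
    n_scenes: int = 4            # nucleus images per condition
    nuclei_per_scene: int = 5
    n_curves: int = 15           # AFM curves per condition
    n_yap_cells: int = 8
    n_fa_particles: int = 40
    curve_noise_frac: float = 0.02   # of max force
    scene_noise_sd: float = 100.0
    pixel_size: float = 0.2      # µm/px

    def as_dict(self) -> dict:
        return asdict(self)


def _condition_outputs(cond: ConditionSpec, cfg: PipelineConfig,
                       rng: np.random.Generator, out: Path) -> dict:
    files = {}
    # --- nuclei: simulate scenes, segment, measure, morphometry
    nuc_rows, desc_list = [], []
    for s in range(cfg.n_scenes):
        scene = synthetic.render_scene(
            cfg.nuclei_per_scene, shape=(512, 512),
            seed=int(rng.integers(2 ** 31)),
            pixel_size=cfg.pixel_size,
            base_spec=synthetic.SyntheticNucleusSpec(
                noise_sd=cfg.scene_noise_sd),
            deformed_fraction=cond.deformed_fraction)
        dapi = scene.image.plane(0, "dapi")
        lamin = scene.image.plane(0, "lamin")
        labels = segment_nuclei(dapi, SegmentationConfig())
        lam_mask = detect_lamina(lamin)
        assigned, _ = split_and_assign_laminae(lam_mask, labels)
        records = measure_intensities(labels, assigned, scene.image)
        for rec in records:
            d = compute_descriptors(rec)
            d.fragmentation_index = fragmentation_index(
                rec.nucleus_mask, rec.lamina_mask)
            classify_deformed(d)
            desc_list.append(d)
        df = records_to_frame(records)
        if not df.empty:
            df.insert(0, "scene", s)
        nuc_rows.append(df)
        if s == 0:
            write_tiff(out / f"{cond.name}_scene0_labels.tif",
                       labels.labels.astype(np.uint16),
                       cfg.pixel_size, scale_to_uint16=False)
            files.setdefault("segmentation", []).append(
                out / f"{cond.name}_scene0_labels.tif")
    nuc_df = pd.concat([d for d in nuc_rows if not d.empty],
                       ignore_index=True) if nuc_rows else pd.DataFrame()
    p = out / f"{cond.name}_nuclei.csv"
    nuc_df.to_csv(p, index=False)
    files.setdefault("segmentation", []).append(p)

    report = summarize_condition(desc_list, cond.name)
    p = out / f"{cond.name}_morphometry.csv"
    descriptors_to_frame(desc_list).to_csv(p, index=False)
    files["morphometry"] = [p]

    # --- focal adhesions
    fa_spec = SyntheticAdhesionFieldSpec(
        n_particles=cfg.n_fa_particles,
        particle_semi_axes_range=cond.fa_axes)
    stack, _truth = render_adhesion_image(
        fa_spec, seed=int(rng.integers(2 ** 31)),
        pixel_size=cfg.pixel_size, n_planes=3)
    best, _scores = select_best_plane(stack, "vinculin")
    fa_records = segment_adhesions(stack.plane(best, "vinculin"), plane=best)
    fa_df = adhesion_records_to_frame(fa_records)
    p = out / f"{cond.name}_adhesions.csv"
    fa_df.to_csv(p, index=False)
    files["adhesions"] = [p]

    # --- YAP ratio
    yap_rows = []
    for c in range(cfg.n_yap_cells):
        spec = SyntheticYapCellSpec(
            nuclear_mean=100.0 * cond.yap_ratio, cytoplasm_mean=100.0,
            noise_sd=5.0)
        img, truth = render_yap_cell(spec, seed=int(rng.integers(2 ** 31)),
                                     pixel_size=cfg.pixel_size)
        r = yap_nc_ratio(img, truth["nucleus_mask"], cell_id=f"{cond.name}_{c}")
        yap_rows.append({"cell_id": r.cell_id, "ratio": r.ratio,
                         "nuclear_mean": r.nuclear_mean,
                         "cytoplasmic_mean": r.cytoplasmic_mean})
    yap_df = pd.DataFrame(yap_rows)
    p = out / f"{cond.name}_yap.csv"
    yap_df.to_csv(p, index=False)
    files["yap"] = [p]

    # --- AFM
    fits = []
    for c in range(cfg.n_curves):
        E = cond.E_kpa * 1e3
        noiseless = simulate_force_curve(SyntheticCurveSpec(E_true=E))
        noise_sd = cfg.curve_noise_frac * float(noiseless.force.max())
        spec = SyntheticCurveSpec(E_true=E, noise_sd=noise_sd,
                                  seed=int(rng.integers(2 ** 31)))
        curve = simulate_force_curve(spec, cell_id=f"{cond.name}_{c}",
                                     condition=cond.name)
        fits.append(afm.fit_hertz(curve))
    fit_df = pd.DataFrame([asdict_fit(f) for f in fits])
    p = out / f"{cond.name}_afm.csv"
    fit_df.to_csv(p, index=False)
    files["afm"] = [p]

    return {"files": files, "morphometry_report": report,
            "fa_records": fa_records, "yap": yap_df,
            "moduli": [f.E for f in fits if f.converged],
            "descriptors": desc_list}


def asdict_fit(f: afm.HertzFitResult) -> dict:
    return {"cell_id": f.cell_id, "condition": f.condition,
            "E_Pa": f.E, "nu": f.nu, "R_m": f.R,
            "contact_point_m": f.contact_point, "baseline_N": f.baseline,
            "n_points_used": f.n_points_used, "rss_N2": f.rss,
            "converged": f.converged}


def run_pipeline(out_dir, seed: int = 0,
                 cfg: PipelineConfig | None = None,
                 conditions: tuple[ConditionSpec, ...] | None = None):
    """Run the full synthetic study and write all tables under ``out_dir``.

    Returns the run report.  Deterministic: a second run with the same
    seed and config reproduces every output byte.
    """
    cfg = cfg or PipelineConfig()
    conditions = conditions or (
        ConditionSpec("control", E_kpa=4.0, deformed_fraction=0.1,
                      fa_axes=(4.0, 8.0), yap_ratio=2.5),
        ConditionSpec("depleted", E_kpa=1.5, deformed_fraction=0.55,
                      fa_axes=(6.0, 11.0), yap_ratio=1.2),
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    per_cond = {c.name: _condition_outputs(c, cfg, rng, out)
                for c in conditions}

    # condition comparison (the study's headline contrasts)
    a, b = conditions[0].name, conditions[1].name
    comparisons = []
    pairs = {
        "youngs_modulus_Pa": (per_cond[a]["moduli"], per_cond[b]["moduli"]),
        "fa_area_um2": ([r.area_um2 for r in per_cond[a]["fa_records"]],
                        [r.area_um2 for r in per_cond[b]["fa_records"]]),
        "yap_nc_ratio": (per_cond[a]["yap"]["ratio"].to_numpy(),
                         per_cond[b]["yap"]["ratio"].to_numpy()),
        "roundness": ([d.roundness for d in per_cond[a]["descriptors"]],
                      [d.roundness for d in per_cond[b]["descriptors"]]),
    }
    for what, (x, y) in pairs.items():
        r = unpaired_ttest(x, y, labels=(a, b))
        comparisons.append({"quantity": what, **r.__dict__})
    comp_df = pd.DataFrame(comparisons)
    comp_path = out / "condition_comparisons.csv"
    comp_df.to_csv(comp_path, index=False)

    deform_df = pd.DataFrame([{
        "condition": c.name,
        "n_nuclei": per_cond[c.name]["morphometry_report"].n_nuclei,
        "percent_deformed":
            per_cond[c.name]["morphometry_report"].percent_deformed,
    } for c in conditions])
    deform_path = out / "percent_deformed.csv"
    deform_df.to_csv(deform_path, index=False)

    stage_outputs: dict[str, list] = {"stats": [comp_path, deform_path]}
    for res in per_cond.values():
        for stage, paths in res["files"].items():
            stage_outputs.setdefault(stage, []).extend(paths)
    report = build_report(stage_outputs, cfg.as_dict(), {"seed": seed}, out)
    return report
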