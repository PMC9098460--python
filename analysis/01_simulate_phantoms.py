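#!/usr/bin/env python
"""Generate one example phantom of each modality with its ground truth.

Writes a multi-nucleus DAPI+lamin scene, a focal-adhesion field, a YAP
two-compartment cell and a Hertzian force curve under results/phantoms/,
each with its exact truth table, so later stages can be inspected
against known answers.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from nucleomech import synthetic as syn
from nucleomech.images import write_tiff

OUT = Path(__file__).resolve().parent.parent / "results" / "phantoms"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)
    OUT.mkdir(parents=True, exist_ok=True)

    scene = syn.render_scene(6, seed=int(rng.integers(2 ** 31)),
                             base_spec=syn.SyntheticNucleusSpec(noise_sd=100.0),
                             deformed_fraction=0.4)
    write_tiff(OUT / "nuclei_scene.tif", scene.image.planes[0], 0.2)
    write_tiff(OUT / "nuclei_truth_labels.tif",
               scene.nucleus_labels.labels.astype(np.uint16),
               scale_to_uint16=False)
    scene.truth.to_csv(OUT / "nuclei_truth.csv", index=False)
    print(f"nuclei scene: {len(scene.truth)} nuclei, "
          f"{int(scene.truth.deformed_true.sum())} with invaginations")

    fa, fa_truth = syn.render_adhesion_image(
        syn.SyntheticAdhesionFieldSpec(), seed=int(rng.integers(2 ** 31)))
    write_tiff(OUT / "adhesion_field.tif", fa.pixels, fa.pixel_size)
    fa_truth.to_csv(OUT / "adhesion_truth.csv", index=False)
    print(f"adhesion field: {len(fa_truth)} particles, "
          f"mean true area {fa_truth.area_um2.mean():.2f} um^2")

    yap_img, yap_truth = syn.render_yap_cell(
        syn.SyntheticYapCellSpec(noise_sd=5.0), seed=int(rng.integers(2 ** 31)))
    write_tiff(OUT / "yap_cell.tif", yap_img.pixels, yap_img.pixel_size)
    write_tiff(OUT / "yap_nucleus_mask.tif",
               yap_truth["nucleus_mask"].astype(np.uint16),
               scale_to_uint16=False)
    (OUT / "yap_truth.json").write_text(
        json.dumps({"ratio": yap_truth["ratio"]}) + "\n")
    print(f"yap cell: true N/C ratio {yap_truth['ratio']:.2f}")

    spec = syn.SyntheticCurveSpec(E_true=2000.0, noise_sd=4e-11,
                                  seed=int(rng.integers(2 ** 31)))
    curve = syn.simulate_force_curve(spec)
    pd.DataFrame({"delta_m": curve.delta, "force_N": curve.force}).to_csv(
        OUT / "force_curve.csv", index=False)
    (OUT / "force_curve_truth.json").write_text(json.dumps(
        {"E_true_Pa": spec.E_true, "contact_shift_m": spec.contact_shift}) + "\n")
    print(f"force curve: {len(curve)} samples, E_true {spec.E_true:.0f} Pa")
    print(f"phantoms written to {OUT}")


if __name__ == "__main__":
    main()
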