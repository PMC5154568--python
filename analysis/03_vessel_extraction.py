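#!/usr/bin/env python
"""Render a flow-map stack, extract vessels, and report MA/MV/MT.

Builds a ground-truth scene (ONH ellipse + radial surface vessels), renders
a noisy frame stack from one subject's pulse, detects cardiac cycles on the
ROI-mean series, forms the composite map, splits vessel from tissue with an
automatic Otsu threshold, and compares the recovered mask with ground truth.
Writes results/vessel_extraction.csv.
"""

from pathlib import Path

import pandas as pd

from lsfg.onh import EllipseRoi, composite_map, extract_vessels, regional_mbr, roi_mask
from lsfg.synthetic import SubjectProfile, generate_flowmap_stack, make_scene
from lsfg.waveform import MbrSeries, detect_cycles

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    profile = SubjectProfile(
        subject_id="DEMO", age=48.0, sex="male", heart_rate=70.0,
        mbr_baseline=7.0, pulse_amplitude=10.0, systolic_rise_fraction=0.30,
        diastolic_decay_tau=0.55, sbp=130.0, dbp=82.0, iop=13.0)
    # reduced raster keeps the demonstration quick; geometry is proportional
    scene = make_scene(seed, shape=(180, 375))
    stack = generate_flowmap_stack(profile, scene, 118, 30.0, seed,
                                   pixel_noise_sd=0.1 * scene.tissue_flow_scale)

    series = MbrSeries(values=stack.frames.mean(axis=(1, 2)), frame_rate=30.0)
    seg = detect_cycles(series)
    cmap = composite_map(stack, seg)
    roi = roi_mask(scene.shape, EllipseRoi(scene.center, scene.semi_axes))
    vessel, thr = extract_vessels(cmap, roi)
    meas = regional_mbr(cmap, roi, vessel, thr)

    truth = roi & scene.vessel_mask
    accuracy = float((vessel[roi] == truth[roi]).mean())
    row = {
        "n_cycles": seg.n_cycles,
        "threshold": round(thr, 2),
        "vessel_fraction": round(meas.vessel_fraction, 3),
        "mask_accuracy": round(accuracy, 4),
        "MA": round(meas.ma, 2), "MV": round(meas.mv, 2), "MT": round(meas.mt, 2),
    }
    OUT.mkdir(exist_ok=True)
    pd.DataFrame([row]).to_csv(OUT / "vessel_extraction.csv", index=False)
    print(pd.DataFrame([row]).to_string(index=False))
    print(f"\nvessel mask recovered with {100 * accuracy:.1f}% pixel accuracy; "
          f"ordering MV > MA > MT holds: {meas.mv > meas.ma > meas.mt}")


if __name__ == "__main__":
    main()
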