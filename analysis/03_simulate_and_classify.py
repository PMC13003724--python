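#!/usr/bin/env python
"""Synthetic rupture-site mapping end to end.

Builds an idealized fusiform aneurysm, plants two rupture-like lesions
whose WSS carriers are constructed to land inside the joint criterion
(TAWSS 0-0.5 Pa, OSI 0.35-0.5, ECAP 1.6-2.0 1/Pa, RRT 24-30), simulates
three cardiac cycles of pulsatile WSS, computes the four indices on the
third cycle, applies the joint criterion and extracts candidate patches.
A healthy straight tube is run as a negative control.

Expected outcome: the classifier recovers both planted lesions as the two
largest patches with Jaccard overlap >= 0.9 against ground truth and the
planted range bins; the healthy tube produces no criterion region at all.
"""

from pathlib import Path

import pandas as pd

from aawss.mesh import cylinder_profile, fusiform_profile, make_vessel_mesh
from aawss.metrics import CycleSpec, compute_fields
from aawss.risk import extract_patches, jaccard, joint_risk_mask, roi_summary
from aawss.synth import LesionSpec, synth_wss_series
from aawss.waveform import make_waveform

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

mesh = make_vessel_mesh(fusiform_profile(0.01, 0.012, 0.06, 0.015),
                        0.12, 48, 72)
wave = make_waveform("generic_aortic", cycles=3)
lesions = [LesionSpec(center=(0.022, 0.0, 0.06), geodesic_radius=0.012),
           LesionSpec(center=(-0.022, 0.0, 0.06), geodesic_radius=0.012)]
series = synth_wss_series(mesh, wave, base_tawss=1.5, lesions=lesions,
                          seed=SEED)
fields = compute_fields(series, CycleSpec(cycle_index=3))
mask = joint_risk_mask(fields)
rmap = extract_patches(mask, mesh, fields)

rows = []
for i, patch in enumerate(rmap.patches):
    best = max(series.ground_truth["lesions"],
               key=lambda g: jaccard(patch["nodes"], g["nodes"]))
    rows.append({
        "patch": i, "n_nodes": len(patch["nodes"]),
        "area_mm2": round(patch["area_m2"] * 1e6, 2),
        "jaccard_vs_planted": round(jaccard(patch["nodes"], best["nodes"]), 4),
        **{f"{p}_bin": patch["modal_bins"][p]
           for p in ("tawss", "osi", "ecap", "rrt")}})
df = pd.DataFrame(rows)
df.to_csv(OUT / "synthetic_patch_recovery.csv", index=False)

print(f"fusiform aneurysm: {mesh.n_nodes} nodes, {int(mask.sum())} "
      f"criterion nodes in {len(rmap.patches)} patches (seed {SEED})")
print(df.to_string(index=False))

healthy = make_vessel_mesh(cylinder_profile(0.01), 0.12, 32, 48)
h_fields = compute_fields(synth_wss_series(healthy, wave, base_tawss=1.5,
                                           seed=SEED))
h_mask = joint_risk_mask(h_fields)
print(f"\nhealthy tube control: {int(h_mask.sum())} criterion nodes "
      f"(expected 0)")
print(f"\nwrote {OUT / 'synthetic_patch_recovery.csv'}")
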