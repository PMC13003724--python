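# aawss

Wall-shear-stress hemodynamic analysis for abdominal aortic aneurysm
(AAA) rupture-risk assessment: per-node TAWSS/OSI/ECAP/RRT computation
from transient CFD wall-shear exports, joint-threshold rupture-site
mapping, Roache grid-convergence-index verification, and patient-cohort
tabulation — together with a synthetic pulsatile-WSS generator so that
every stage can be exercised and validated without a CFD solver.

## Who this is for

Ruptured AAAs are frequently smaller than the 5.5 cm surgical threshold,
so diameter alone under-predicts risk.  Flow-induced wall shear stress
(WSS) indices computed from patient-specific CFD localize the disturbed
hemodynamics believed to degrade the arterial wall.  This package covers
the *post-processing* side of that workflow: it consumes per-node WSS
vector time series (e.g. `WSSx, WSSy, WSSz` exported from a CFD
post-processor) and produces index fields, risk maps and summary tables.
The flow solve itself is out of scope.

## The indices and the rupture criterion

With τ_w(t) the instantaneous WSS vector at a wall node over one cardiac
cycle of length T:

- **TAWSS** = (1/T) ∫₀ᵀ |τ_w| dt  (Pa) — time-averaged shear magnitude;
- **OSI** = ½ (1 − |∫₀ᵀ τ_w dt| / ∫₀ᵀ |τ_w| dt) ∈ [0, 0.5] — directional
  oscillation of the shear (0 unidirectional, 0.5 zero-mean);
- **ECAP** = OSI / TAWSS  (Pa⁻¹) — thrombogenic susceptibility;
- **RRT** = 1 / |(1/T) ∫₀ᵀ τ_w dt| = 1 / ((1 − 2·OSI)·TAWSS)  (Pa⁻¹) —
  relative residence time of blood near the wall.

Candidate rupture sites are the surface regions where all four conditions
hold **simultaneously**: TAWSS 0–0.5 Pa, OSI 0.35–0.5, ECAP 1.6–2.0 Pa⁻¹
and RRT 24–30.  Integration uses composite trapezoid on the uniform
0.01 s grid, and by convention the third of three simulated cycles is
analyzed (the first two wash out initial transients).

Mesh adequacy is verified with the grid convergence index: for element
counts N₁ > N₂ > N₃ and solution values φ₁, φ₂, φ₃,
r₂₁ = (N₁/N₂)^⅓, the observed order p solves the standard fixed point,
GCI₂₁ = 1.25·|φ₁−φ₂|/|φ₁|/(r₂₁ᵖ−1)·100%, and the asymptotic-range
diagnostic AR = GCI₃₂/(r₂₁ᵖ·GCI₂₁) should sit near 1.

## Worked example

A three-grid convergence study straight from the command line:

```sh
$ aawss gci --n 2.6893e6 1.1046e6 0.4501e6 --phi 0.48797 0.48954 0.49145
r21=1.345 r32=1.349 p=0.628 s=+1
GCI21=1.964% GCI32=2.359% AR=0.997
Richardson extrapolate: 0.484352
```

Both GCIs are below the usual 5% threshold and AR ≈ 1, so the medium
grid is spatially converged and the 1.25 safety factor is justified.

End-to-end synthetic rupture-site mapping (`analysis/03_simulate_and_classify.py`):

```
fusiform aneurysm: 3504 nodes, 146 criterion nodes in 2 patches (seed 42)
 patch  n_nodes  area_mm2  jaccard_vs_planted tawss_bin  osi_bin ecap_bin rrt_bin
     0       73    348.79                 1.0     0-0.5 0.35-0.5    1.6-2   24-30
     1       73    348.79                 1.0     0-0.5 0.35-0.5    1.6-2   24-30

healthy tube control: 0 criterion nodes (expected 0)
```

Two lesions planted inside the joint criterion are recovered exactly
(Jaccard 1.0 against ground truth, all four modal bins as planted), while
a healthy uniform-shear tube triggers no false positives.

The other numbered drivers under `analysis/` produce the mesh/time-step
verification tables (`01`) and the 22-patient cohort summary (`02`);
each writes its tables to `results/`.

## Layout

- `src/aawss/` — library: `mesh`, `waveform`, `viscosity`, `womersley`
  (analytic pulsatile-flow oracle), `synth` (lesion-planting WSS
  generator), `metrics`, `risk`, `gci`, `cohort`, `io`, `cli`.
- `analysis/` — numbered narrative drivers writing tables to `results/`.
- `tests/` — unit, property and end-to-end acceptance tests.
- `docs/methods.md` — modeling assumptions, conventions and limitations.
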