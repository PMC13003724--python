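# Methods

## Scope and model

The package post-processes transient wall-shear-stress (WSS) vector
fields on triangulated vessel surfaces into the four cycle-averaged
indices TAWSS, OSI, ECAP and RRT, maps the joint four-parameter rupture
criterion into contiguous surface patches, verifies discretization
adequacy with the Roache/Celik grid convergence index (GCI), and
tabulates a patient cohort.  It deliberately contains no flow solver:
the WSS inputs come either from an external CFD export (long-format CSV
of `node_id, t, wss_x, wss_y, wss_z`) or from the built-in synthetic
generator.

## Index computation

- `|τ_w|` in the TAWSS integrand is the **Euclidean norm of the
  instantaneous 3-vector**.  Component-wise absolute values would break
  the OSI ratio bound (the averaged-vector magnitude could exceed the
  averaged magnitude), so the vector-norm reading is used and stated here
  prominently.
- Integration is composite trapezoid on the uniform grid including both
  cycle endpoints — second order, exact for the sampling convention used
  (Δt = 0.01 s, T = 1.0 s, 100 samples/cycle).  Halving Δt reduces the
  quadrature error ~4×, which the tests assert.
- Multi-cycle series carry `cycles × T/Δt` samples (no duplicated
  endpoint).  `extract_cycle` returns `T/Δt + 1` samples by closing the
  requested cycle periodically (repeating the cycle-start sample at
  t_end) when the explicit end sample is absent; this is exact for
  periodic signals, which all generated series are.  The **third of
  three cycles** is analyzed by default to discard start-up transients.
- Degenerate nodes are flagged, never silently NaN: TAWSS = 0 leaves
  OSI/ECAP undefined (reported 0 with a flag); a cycle-mean vector at or
  below 10⁻¹² × TAWSS is treated as zero, giving OSI = 0.5 and an
  infinite-RRT flag.  RRT is computed from the mean-vector magnitude and
  cross-checked against 1/((1−2·OSI)·TAWSS) at 10⁻⁹ relative tolerance
  (plus a 10⁻¹²·TAWSS absolute floor against cancellation noise);
  disagreement raises an internal-consistency error.
- RRT carries Pa⁻¹ internally; reported ranges (18–24, 24–30) treat it
  as a plain number, matching clinical reporting practice.
- For display, fields are clipped at TAWSS 5 Pa, OSI 0.5, ECAP 2 Pa⁻¹,
  RRT 30 (`clamp_for_report`); raw values are preserved.

## Risk binning and patch extraction

- Bins are half-open `[lo, hi)`; the topmost bin is closed above.
  Values beyond the top edge are assigned to the top bin with an
  overflow flag, consistent with capped contour color scales.  The
  boundary convention is configurable; this default is documented
  because the reporting convention is not otherwise fixed.
- The joint criterion is the pointwise AND of the four range conditions;
  flagged nodes are always excluded.
- Patches are maximal components of the masked nodes connected through
  mesh *edges* (vertex-only contact does not bridge), computed with a
  sparse connected-components pass.  Patches under 25 mm² (configurable,
  0 disables) are reported separately as speckle.  Ordering is by area
  descending, ties by lowest node index.
- `roi_summary` reports, per parameter, the **area-weighted modal bin**
  within a region of interest — the explicit convention used to reduce a
  patch to one range entry per parameter, since visual contour reading
  does not define one.

## GCI verification

The printed form of the observed-order relation in common typeset
sources is frequently garbled; the standard Celik fixed point is
implemented: p = |ln|ε₃₂/ε₂₁| + q(p)| / ln r₂₁ with
q = ln((r₂₁ᵖ − s)/(r₃₂ᵖ − s)) and s = sign(ε₃₂/ε₂₁), iterated with 0.5
damping from the q = 0 initial guess to |Δp| < 10⁻¹⁰ (≤ 200 iterations);
the damping prevents oscillation in s = −1 cases.  r₂₁ and r₃₂ are
computed independently (not pooled), Fs = 1.25, and the Richardson
extrapolate is emitted as an auxiliary output.  On synthetic power-law
data φ(h) = φ* + C·hᑫ with exact ratios the recovered order matches q to
10⁻⁸.  The time-step check divides by the **finer**-step value — the
convention back-solved from the packaged reference table, whose printed
percentages truncate (not round) at three decimals.

## Synthetic data generator

The generator emulates the statistical structure of aneurysmal WSS
fields — a predominantly axial, unidirectional pulsatile background with
localized oscillatory, low-magnitude lesions — not their fluid dynamics.

- **Geometry**: surfaces of revolution (open tubes, Euler characteristic
  0) with Gaussian fusiform dilation or an azimuthally localized
  saccular bulge; a 1-D quadrature of 2π∫r√(1+r′²)dz serves as the
  independent area oracle.  Lengths in meters; a 1 cm base radius and
  ~1 cm bulge mimic AAA scale.
- **Waveform**: the literature inlet profiles used in clinical CFD are
  not numerically tabulated, so a parametric two-phase pulse (half-sine
  systolic peak over a diastolic plateau, systole fraction 0.35) stands
  in.  The default 0.45 m/s peak places a 2-cm-diameter vessel at peak
  Reynolds ≈ 2700, inside the transitional 2000–3000 band reported for
  such flows.  One cycle is synthesized and tiled, so periodicity across
  cycles is exact to the bit.
- **Lesion planting**: each lesion node gets an axial carrier
  c + d·sin(2πt/T).  c = (1−2·OSI*)·TAWSS* fixes the discrete cycle mean
  exactly; d is solved by Brent root-finding on the *discrete trapezoid*
  mean-magnitude functional so the computed TAWSS equals TAWSS* to
  solver precision (≈ 10⁻¹⁵, well inside the 10⁻⁶ recovery requirement).
  Targets are drawn per node from the lesion's bins by rejection
  sampling constrained to the region where the implied ECAP and RRT also
  fall in their bins; bin sets admitting no such region are rejected at
  construction.  This makes downstream recovery tests exact rather than
  statistical.
- **Background**: the waveform normalized to unit discrete cycle-mean
  magnitude, scaled by a per-node base TAWSS (default 1.5 Pa — a healthy
  supra-criterion shear level) with ±5% seeded spatial variation;
  strictly positive, hence OSI = 0 outside lesions.
- Everything is deterministic under a fixed seed (bit-identical series).

What passing tests on these fields do **not** show: fidelity of any real
aneurysm's secondary flows, turbulence transition, ILT remodeling or
inter-patient geometric variability.  They validate the *estimators and
the classifier*, not a flow model.

- **Womersley oracle**: the rigid-tube pulsatile solution
  τ_w(t) = Re{(A/β)·J₁(βR)/J₀(βR)·e^{iωt}}, β² = −iωρ/μ, with the steady
  harmonic contributing the Poiseuille wall shear AR/2 ≡ 4μU/R.  It is
  validated against the quasi-steady limit (α → 0) and one-sided finite
  differences of the analytic velocity profile at the wall, and provides
  the independent route for checking the metric pipeline on physically
  structured signals.  Defaults ρ = 1047 kg/m³ and μ = 0.0035 Pa·s (the
  Newtonian high-shear limit of blood).
- **Viscosity**: Bird–Carreau μ(γ̇) = μ∞ + (μ₀−μ∞)[1+(λγ̇)²]^((n−1)/2)
  with plateaus μ₀ = 0.056, μ∞ = 0.0035 Pa·s.  λ = 3.313 s and
  n = 0.3568 are literature-conventional blood-fit values, exposed as
  parameters; only the plateaus are treated as fixed ground truth.

## Cohort module

Descriptive statistics only (no inferential tests are in scope):
prevalences, per-range histograms, size/age summaries, with half-up
rounding to one decimal to match printed reporting style.  The packaged
22-patient table encodes rupture status (19 ruptured, 3 impending —
patients 4, 16 and 17) from the narrative case descriptions, as status
is not a column of the published summary table.  The published age
dispersion (±33.9 y) is inconsistent with the tabulated ages (empirical
SD ≈ 16); only the mean (64.9 y) is reproduced.

## Problem sizes and numerical choices

Test and analysis meshes run at 8×8 to 48×72 (axial × circumferential)
resolution — a few hundred to ~3500 nodes, with 300 time samples — where
lesion recovery is already exact by construction and patch extraction is
unambiguous; the estimators are resolution-independent per node, so
larger meshes change cost, not behavior.  The reference quadrature for
oracle comparisons uses 10⁴ samples/cycle.  File writers use fixed
scientific formatting so identical runs are byte-identical; mesh STL I/O
goes through trimesh, and VTK output is legacy ASCII polydata for broad
viewer compatibility.

## Known limitations

- No Navier–Stokes/turbulence solve, CT segmentation, ILT geometry or
  wall-mechanics (structural stress) modeling.
- The synthetic lesion carrier is single-harmonic and axial; real
  rupture-site WSS has multi-directional, broadband content.
- The joint criterion thresholds are taken as given, not re-derived; the
  package evaluates and maps them.
- `extract_cycle` assumes the series is cycle-periodic when it closes
  the final cycle; for genuinely aperiodic inputs supply the explicit
  end sample.
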