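# Methods

## Signal model and T1 mapping

A Look-Locker acquisition samples the longitudinal magnetization repeatedly
after one adiabatic inversion. The continuous low-flip-angle readout
(flip angle α, image repetition time TR_img) drives the recovery toward a
reduced steady state, so the magnitude signal follows

    S(t) = | A − B·exp(−t/T1*) |,  A = M0*,  B = M0 + M0*,

with an effective time constant 1/T1* = 1/T1 − ln(cos α)/TR_img and steady
state M0* = M0·T1*/T1. These two relations make the classical correction
T1 = T1*(B/A − 1) exact, which is also why the noiseless round trip
(forward model → fit → correction) recovers T1 to numerical precision and
is used as a pipeline self-check.

Fitting is per voxel on magnitude data. Because magnitude loses the sign of
the inverted magnetization, the points before the zero-crossing must be
sign-flipped before fitting the signed model A − B·exp(−t/T1*). The
crossing index is not known in advance; candidates at and adjacent to the
magnitude minimum are tried — including the "no crossing in the sampled
window" and "crossing beyond the last sample" cases, which occur for long
T1 under the short 28-point in vivo readout — and the restoration with the
smallest residual wins. Each candidate is fitted by variable projection:
for fixed T1* the model is linear in (A, B), so the amplitudes are solved
in closed form and a bounded 1-D search over log T1* (bounds 1 ms–20 s,
covering tissue, gel and buffer) minimizes the profiled residual. A global
sign flip of (A, B) is unobservable in magnitude data and is normalized to
positive amplitudes. Voxels are rejected (flagged, counted, excluded from
maps) when A ≤ 0, B ≤ A, T1* pegs a bound, or the relative residual
exceeds 20%; all-zero voxels (background) are flagged rather than errors.

Acquisition constants follow the two protocols the phantoms emulate:
in vitro 100 inversion times at TR_img 25 ms (first at 10 ms), flip 5°,
2 averages; in vivo 28 inversion times, otherwise identical, 24 averages.
Both are metadata on the series object; the fitter is protocol-agnostic.

## Relaxivity and concentration

A paramagnetic agent adds to the longitudinal relaxation rate linearly:
R1 = R1(0) + r1·[CA]. Calibration ladders (default: the four-step
0.093–0.74 mg/mL ladder converted at 74 kDa) are fitted two ways: the
per-sample estimator r1ᵢ = (1/T1ᵢ − 1/T1₀)/[CA]ᵢ averaged with its SD, and
an OLS regression of R1 on concentration with free intercept (default; the
intercept is reported against the measured blank rate as a consistency
diagnostic). The two agree exactly on noiseless linear data. Concentration
maps invert the same relation, [CA] = (R1 − R1_blank)/r1; values slightly
below zero (noise) are clipped to zero and counted only within a stated
tolerance, so genuine inconsistencies stay visible.

All concentrations are per agent molecule, not per gadolinium ion: the
agent carries ~10–15 Gd per albumin, and relaxivities near 95 mM⁻¹s⁻¹ are
only meaningful on the per-molecule scale. The 74 kDa molecular weight
converts mM ↔ mg/mL exactly.

## Segmentation and ROI system

Gel volumetry uses deterministic region growing: the initial reference is
the mean over the seed voxel's 3×3×3 neighborhood; each pass accepts every
voxel connected (6- or 26-neighborhood) to the current region whose value
lies within a fractional tolerance band around the running region mean
(band fixed during the pass), iterating to a fixed point. Defining each
pass as a set operation makes the result independent of voxel visiting
order. Defaults: 20% tolerance on intensity images, 15% on T1 maps,
6-connectivity. A seed inconsistent with its own neighborhood returns a
single-voxel mask with a warning. Volumes are voxel count × voxel volume
(1 mm³ = 1 µL).

The ROI system reproduces the analysis protocol: the gel core is the
segmented gel eroded by 2 passes of the city-block (3-D cross) structuring
element — "2 voxels from the rim" means two erosion iterations — excluding
the partial-volume band along the gel boundary; the adjacent-tissue ring
starts 10 dilation passes beyond the gel rim (width 2 by default); both are
mirrored across the grid's midline plane for contralateral references.
Mirroring is an index reflection, so mirrored ROIs have exactly the voxel
counts of their sources and mirroring is an involution. For multi-slice
maps whose 1 mm slice thickness dwarfs the ~0.15 mm in-plane voxels, the
morphology can be restricted in-plane (`planar_axis`), matching how ROIs
are drawn per slice in practice; the pipeline uses this for brain-slice
geometry. The midline is the grid's center plane — adequate for phantoms,
and documented as a simplification for real anatomy.

## Release kinetics

With C(t) the mean gel concentration (rim-excluded core ROI) and V(t) the
segmented gel volume, the gel's agent mass is C·V and cumulative release
relative to the first scan t₁ is

    release(t) = 100·(1 − C(t)V(t) / (C(t₁)V(t₁)))   (volume-corrected)

the apparent variant freezes V at V(t₁), so swelling masquerades as release
in it. Both are zero at t₁ by construction and invariant to concentration
and volume unit rescaling.

Diffusion-controlled (Higuchi-type) release is linear in √t at early
times; the rate constant k (% per h^½) is the OLS slope of release on √t
with a free intercept (an initial burst would otherwise bias the slope —
whether to include an intercept is a genuinely open choice, and the free
intercept is the conservative one). An optional pooled regression with a
group × √t interaction compares two formulations' slopes.

The diffusion coefficient inverts the early-time solution for desorption
from a plane slab, Mt/M∞ = P·√(Dt/(π·L_d²)) with prefactor P = 4. The tube
gel releases only through its top face (the tube base and walls are
impermeable), which is the half-problem of a symmetric slab of twice the
thickness: the diffusional thickness is L_d = 2L for one-sided geometry
(L = 5.5 mm slab) and L_d = L for two-sided. Both prefactor and geometry
are explicit, configurable arguments, and the exact eigenfunction series

    Mt/M∞ = 1 − Σₙ 8/((2n+1)²π²)·exp(−(2n+1)²π²·D·t/L_d²)

(default 200 terms) serves as the independent oracle: below 40% release
the early-time law agrees with the series to well under 2%, and the round
trip D → simulated release → √t fit → D closes to within a few percent
(quadrature error of sampling a √t curve at discrete times).

Mesh size uses the affine rubber-elasticity estimate ξ = (RT/(G′·N_A))^⅓,
with G′ the plateau storage modulus (mean over the final 20% of a gelation
time sweep), T = 310.15 K by default, R = 8.314 J mol⁻¹ K⁻¹ and
N_A = 6.022×10²³ mol⁻¹. Release is classified "diffusive" when the
solute's hydrodynamic diameter (albumin: 7.2 nm) is below ξ, else
"hindered". G′ ≈ 3.0/6.3 kPa gives ξ ≈ 11.3/8.8 nm, both above 7.2 nm.

In vitro–in vivo comparison interpolates both corrected-release curves
linearly at shared times and tabulates paired differences and ratios;
extrapolation outside either observed span is refused.

## Synthetic phantoms

The raw image data the pipeline was designed for are serial acquisitions
of (a) PCR tubes with 40 µL gel under 160 µL PBS and (b) rat brains with a
5 µL intrastriatal gel deposit. The phantom module renders both setups
with fully known truth:

- **Tube**: a cylindrical gel slab (cross-section fixed by the nominal
  40 µL / 5.5 mm slab, height tracking the prescribed V(t)) under a
  supernatant column. Gel concentration evolves as mass/(rendered volume)
  with mass following the exact Fickian series (one-sided, the prescribed
  D); released mass accumulates in the supernatant until refresh events
  (default: 24 h before each daily scan) zero it instantaneously, the
  gel's state carrying over. Agent mass is conserved across gel,
  supernatant and refresh-removed pools to 10⁻⁹ relative. Voxel T1 follows
  1/T1 = 1/T1_blank + r1·C in both compartments.
- **Brain-slice**: an ellipsoidal deposit in a uniform-T1 tissue grid;
  V(t) is rendered by morphological dilation/erosion of the initial mask
  toward the target voxel count (full passes, then boundary voxels nearest
  the centroid, deterministically ordered), preserving the shape class.
  Optional shells emulate the tissue reactions seen around implanted gels:
  a short-T1 rim and a longer-T1 peri-gel band (fluid accumulation).

The gel is well mixed within each phantom: the internal diffusion profile
is *not* rendered, so ROI means equal the true compartment concentration
and the noiseless pipeline must close exactly — that is the point of the
oracle. Consequences: passing phantom tests demonstrates correctness of
the estimation chain, not robustness to intra-gel gradients, partial
volume at real interfaces, B1 inhomogeneity, or motion, none of which are
modeled (no Bloch simulation, no k-space artifacts).

Noise is Rician by default (magnitude MRI: independent Gaussian noise on
both quadratures before the modulus), Gaussian optionally for linear-
regime tests; σ is a fraction of unit proton density per average, reduced
by √n_averages per the protocol (2 in vitro, 24 in vivo). All randomness
flows from one integer seed per phantom; identical specs and seeds give
bit-identical output.

Preset specs encode the study conditions: LC (low-concentration, 81%
water) tubes near-stable around 40 µL with D = 7.0×10⁻¹¹ m²/s (the value
implied by a 10.3 %/h^½ rate constant at L = 5.5 mm); HC (66% water)
tubes swelling toward ~55 µL by 24 h and ~60 µL by endpoint with
D = 3.7×10⁻¹¹ (from 7.5 %/h^½); brain deposits starting at 5.3 µL, the
LC-like one swelling to ~10.8 µL by day 7 then receding, the HC-like one
growing to ~21.6 µL by day 21, with faster effective release than their
tube counterparts. Blank-gel T1 presets are 2.2/2.0 s (tube LC/HC) and
2.6/2.4 s (brain), against 2.5 s PBS and 1.7 s striatal tissue — the
brain values sit higher so late-time gel/tissue contrast supports
T1-based volumetry, matching the bright appearance of spent gels on late
T1 maps. Phantom grids are scaled-down acquisition matrices (tube
16×16×26 at 0.4×0.4×0.5 mm; brain 40×40×5 at 0.15×0.15×1 mm, the
in vivo in-plane resolution) — chosen so a full multi-phantom run
completes in minutes while every geometric feature (rim bands, offset
rings, mirrors, slice quantization) remains resolvable.

## Numerical choices and limitations

- Variable projection makes the voxel fit convex-in-amplitudes with a
  smooth 1-D profile; the bounded scalar search uses xatol 10⁻¹⁰ in
  log T1*.
- Gel volumes are quantized to whole slices (tube) or voxels (brain);
  noiseless segmented volumes match truth exactly by construction, and
  release closes because truth concentrations are defined against rendered
  volumes.
- The sqrt-time fit window defaults to the first 24 h; the fit requires
  ≥ 3 points.
- Release percentages are rebased to the first acquisition ("% of the dose
  present at t₁"), matching the definition used for corrected release;
  the absolute since-gelation fractions remain available on the truth
  object.
- The rubber-elasticity mesh estimate assumes an affine, ideal network;
  it is an order-of-magnitude tool, and the diffusive/hindered verdict
  inherits that roughness.
- Degradation kinetics are not modeled (none expected within the 21–27 day
  observation windows); the IVIVR difference in the presets is emulated
  purely as a larger effective diffusivity.
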