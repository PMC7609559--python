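# Methods

This note documents the models behind `coarctflow`, the defaults and why
they were chosen, the numerical scheme, and what the synthetic data do and
do not emulate.

## Reference cohort

`coarctflow.load_reference_cohort()` returns a 20-patient cohort of
adolescents and young adults with aortic coarctation, transcribed from the
per-patient tables of a published MRI-ergometry/CFD study. Each patient
carries clinical measurements (BSA, sex, age, cuff pressures, heart rate,
stroke volume, peak-systolic ascending/descending flow, each at rest and
during exercise) and the CFD-derived descriptors (transstenotic gradient,
surface-averaged WSS in the ascending aorta, SFD and NFD at the ascending
and descending stations).

Transcription fidelity: the source prints gradients rounded to 1 mmHg and
WSS to 0.1 Pa, so cohort means recomputed from the table agree with the
published summary statistics within that input rounding (e.g. mean gradient
18.0 vs 17.99 mmHg, WSS 20.33 vs 20.33 Pa), and the 20 mmHg threshold
partition (6 above in both conditions / 8 below in both / 6 crossing under
exercise) is reproduced exactly. Two caveats are inherent to the available
source text and are not correctable from it: the heart-rate columns and two
of the flow columns contain cells that cannot be reconciled with the
published column means and SDs (most prominently, the exercise heart-rate
SD); consequently the recomputed mean cardiac index at rest is 3.77 l/min/m²
against a published 3.67. All other published summary rows (blood pressure,
stroke volume, SVI, resting ascending flow, all CFD descriptors) are matched
to their printed precision. The affected cells are kept exactly as
transcribed rather than adjusted to fit the published summaries.

## Synthetic cohort and measurement planes

`synthetic.CohortDistributionSpec` encodes the study population: stenosis
degree 35.1 ± 18.1 % (truncated to (0.02, 0.95)), BSA 1.6 ± 0.4 m², heart
rate 72.9 ± 14.2 bpm at rest with an exercise target of +50 bpm of which
85.79 ± 10.28 % is achieved, stroke-volume index 50.6 ± 6 ml/m², ascending
peak-systolic flow 407 ± 87.3 ml/s at rest. Values without published
per-patient spread use modeling choices flagged here: the exercise/rest
flow ratio is lognormal about the cohort ratio 494.4/407 with log-SD 0.15;
the descending/ascending flow fraction is normal about 225.5/407 with
SD 0.12 (the study reports this ratio as unchanged by exercise, so it is
held fixed per patient); truncated-normal sampling is by rejection; the
per-patient RNG is seeded as `seed + patient_index` so cohorts are
reproducible and individual patients re-derivable.

Each patient carries velocity-encoded measurement planes at the sinotubular
junction, mid-ascending and descending stations, for rest and exercise, on
a 64 × 64 grid over the lumen's bounding square (≈ 0.3 % discretization
error on the metrics). The through-plane profile is a blunt jet
u(ρ′) = U(1 − (ρ′/R)^k) clipped at zero, displaced by d·R, with k = 4 by
default (peak-systolic aortic profiles are flatter than parabolic), scaled
so the noise-free lumen integral matches the patient's flow exactly. The
in-plane component is a solid-body swirl whose amplitude is chosen by
discrete quadrature so the noise-free SFD equals the drawn target exactly.
Gaussian noise (0.05 m/s at rest, 0.10 m/s under exercise — exercise
acquisitions average fewer heartbeats and are noisier) is added per
component inside the lumen; velocity-encoding aliasing wraps every
component into (−venc, venc], with venc 3 m/s for milder and 4 m/s for more
severe stenoses.

What the generator does **not** emulate: pulsatile waveforms, k-space/MR
physics, motion/respiratory artifacts, eccentric or non-circular lumens,
correlated (structured) noise. Passing the recovery tests therefore shows
the metric implementations are correct and noise-robust on idealized
planes; it does not validate them against scanner data.

Estimator caveats established by the noise study (and asserted in tests):
the velocity-max NFD variant is biased upward under noise (the argmax of a
noisy field wanders; at 0.05 m/s noise the bias is ≈ +0.13 R) — it is the
default because it matches the descriptor's usual definition on smooth CFD
fields, but the flow-centroid variant, which is unbiased under additive
noise, should be preferred for noisy measured planes. The SFD estimator
carries the folded-normal (Rician) bias of order σ²/(2·mean in-plane
speed), about +0.5 % at study noise.

## Vessel geometry and mesh

The patient anatomy is reduced to an axisymmetric straight vessel of
reference radius 10 mm and length 0.20 m with a C¹ cosine-bump narrowing
r(z) = R(1 − D cos²(π(z − z_s)/l_s)) on |z − z_s| ≤ l_s/2; the diameter-
based degree of stenosis is exactly D. The arch curvature and discrete
branch vessels are not representable in axisymmetry; branch outflow is
extracted through a wall suction band at z ∈ [0.06, 0.09] m. The default
bump length l_s = 40 mm keeps the peak wall slope π·D·R/l_s below ≈ 0.45
for D ≤ 0.55, which is the non-orthogonality range in which the solver is
robust (see Limitations).

The structured grid is body-fitted: vertical stations in z, radial
surfaces scaled to r(z). Sizing follows clinical-CFD practice: base cell
size 0.4 mm; three wall layers of total thickness one third of the base
size, each layer 50 % thicker than the one below (t, 1.5t, 2.25t with
4.75t = Δ/3, i.e. 28.07/42.11/63.16 µm at Δ = 0.4 mm), held at fixed
physical thickness at every station; axial spacing refined toward 0.1 mm
where |dr/dz| exceeds 0.5. Cell volumes are exact solids of revolution for
the linear-in-z surfaces, so the mesh volume converges to the analytic
vessel volume at second order (≤ 0.5 % at default resolution).

## Boundary conditions

The inlet receives the measured plane's through-plane component,
azimuthally averaged to a radial profile, linearly interpolated onto the
inlet faces (zero outside the measured lumen, consistent with no-slip) and
rescaled by a single factor so the discrete inlet flux equals the measured
ascending flow; a pre-rescaling mismatch above 25 % raises a warning, the
analogue of falling back to a 2-D acquisition when the 4-D plane is
degraded. The descending flow sets the outlet budget, and the difference
leaves through the suction band at a uniform outward normal velocity
(flux / band lateral area). Budget closure (inlet = sink + outlet) is
enforced to 0.1 %.

The arch-branch split itself is diagnostic only (the axisymmetric solver
sees a single band): the branch total is divided 1/2 to the brachiocephalic
trunk (it supplies two beds — right arm and head) and 1/4 each to the left
common carotid and left subclavian; an equal-thirds rule is selectable.
Below the arch level, every bifurcation splits flow in proportion to
radius cubed (Murray's law); terminal flows always sum to the input and
the split is invariant under a common radius rescaling. A verification
helper `developed_inlet` provides the discrete fully-developed profile of
the solver's own radial stencil (the analogue of a periodic inflow),
used by the Hagen-Poiseuille verification so that no slow entrance
transient contaminates the comparison.

## Rheology

Blood is a generalized-Newtonian Carreau–Yasuda fluid,
μ(γ̇) = μ∞ + (μ0 − μ∞)[1 + (λγ̇)^a]^((n−1)/a), with whole-blood constants
μ0 = 0.16 Pa·s, μ∞ = 3.5 mPa·s, λ = 8.2 s, a = 0.64, n = 0.2128 — the
parameter set commonly used in aortic CFD. All constants are configuration,
not ground truth; a fixed-viscosity Newtonian model is provided for
verification. μ is monotone non-increasing in γ̇ and bounded by the two
plateaus for any valid parameters. The scalar shear rate is γ̇ = √(2 D:D)
from the axisymmetric rate-of-deformation tensor, including the hoop
component v/r. Density defaults to 1050 kg/m³.

## Flow solver

Steady, laminar, incompressible, axisymmetric finite volumes on the
body-fitted grid; cell-centred (collocated) variables with Rhie–Chow face
interpolation and SIMPLE pressure–velocity coupling. A collocated
arrangement was chosen over a staggered one because face geometry on the
body-fitted grid is then needed only once, and Rhie–Chow damping provides
the same checkerboard control; this is the standard choice of modern
unstructured codes. Convection is first-order upwind; diffusion uses the
over-relaxed orthogonal split with deferred non-orthogonality corrections;
the full deviatoric stress is kept — the transpose-gradient terms are
applied as deferred fluxes on interior *and* boundary faces (omitting the
boundary faces leaves spurious momentum sources in the first/last cell
rows that advect through the whole domain at high Reynolds number). The
radial momentum carries the implicit hoop sink 2μv/r²; the symmetry axis
needs no special treatment because revolved face areas vanish at r = 0.
Green–Gauss gradients are computed with planar (z, r) cell geometry —
using revolved areas there is a subtle error that corrupts the radial
gradient near the axis.

Boundary conditions: prescribed inlet velocity profile; no-slip rigid wall
with prescribed outward suction on the branch band; fixed-pressure outlet
(gauge, outlet-referenced), which anchors the pressure level and lets the
outlet flow emerge from mass conservation as inlet − sink. Under-relaxation
0.7 (velocity) / 0.3 (pressure) / 0.5 (viscosity); normalized residual
tolerance 10⁻⁶ (momentum scaled by the inlet momentum flux ρQU, continuity
by ρQ); maximum 20 000 outer iterations; residual growth beyond 10⁶ raises
a divergence error carrying the history. Zero inflow with zero sink returns
the exact rest state. Every run reports its inlet Reynolds number because
the laminar model is the central desk-scale approximation: the clinical
workflow this package mirrors used a k–ω SST turbulence model on
patient-specific 3-D anatomies, and exercise flows in real aortas are
transitional. Patient-scale pressure gradients are therefore **not**
reproducible here; the solver's purpose is verified physics (Poiseuille to
< 0.2 %, second-order grid convergence, exact mass budgets) and correct
qualitative behaviour (gradient strictly increasing with flow through a
stenosis).

Wall shear stress is extracted in post-processing as τ_w = μ(γ̇_w)|∂u_t/∂n|
with a one-sided second-order difference across the two wall-adjacent
graded layers, and surface-averaged with 2πr arc weights; the "ascending
aorta" segment defaults to [inlet, branch-band start].

## Hemodynamic descriptors

ΔP: P₁ is the area-averaged pressure of the inlet-side column; P₂ the
maximum area-averaged pressure over columns downstream of the throat
(plane of maximal pressure recovery); the gradient is floored at zero and
reported in mmHg (133.322 Pa/mmHg). SFD and NFD operate on measurement
planes as defined in the README; NFD's velocity-max tie-break picks the
masked point nearest the lumen center, and both variants are clipped to
[0, 1]. CI and SVI are per-patient arithmetic on clinical units.

## Statistics

Normality of the paired differences is tested with Shapiro–Wilk; p ≥ 0.05
routes to the paired t-test, otherwise to the Wilcoxon signed-rank test
(zeros dropped; exact null distribution for n ≤ 25 without rank ties,
normal approximation with continuity correction otherwise — the exact
branch is validated against full sign-assignment enumeration). Percent
change is the mean of per-patient relative changes (this convention, not
the ratio of means, reproduces the published percent-change pattern given
integer-rounded gradients: ≈ 75 % vs the published 73.53 %); the ratio of
means is reported alongside. Threshold classification uses strict ">" at
20 mmHg, which reproduces the published 6/8/6 partition, and counts reverse
crossings separately. No multiple-testing correction is applied. Note that
the Shapiro–Wilk router selects the t-test under truly normal differences
with probability exactly 1 − α = 0.95, so observed routing rates over a
finite number of replicates fluctuate around 95 % with binomial error.

## Limitations

- Axisymmetric, laminar, rigid-walled, peak-systolic steady flow: arch
  curvature, turbulence, wall compliance and pulsatility are all outside
  the model; absolute gradients are not comparable to patient values.
- The collocated scheme loses robustness when the wall slope |dr/dz|
  exceeds ≈ 0.5 (the explicit skewness corrections in the 28 µm wall layers
  become dominant); geometry defaults keep slopes below that, and steeper
  vessels should be lengthened (`stenosis_length`) accordingly.
- The velocity-max NFD and the SFD are biased on noisy planes (see above).
- The reference cohort's heart-rate and two flow columns carry
  transcription uncertainty inherited from the source text (see above).
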