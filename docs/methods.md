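# Methods

## The problem

A single line seen through a circular aperture and moving in depth poses
a three-dimensional aperture problem.  Each eye measures only the
image-motion gradient — the velocity component perpendicular to the
line's image — so monocular motion leaves the line's true velocity
ambiguous.  Inverse projection of each eye's 2D velocity constraint
through its nodal point yields a *constraint plane* in space; the two
planes intersect in a line, the intersection of constraint planes (ICP),
which collects every 3D velocity consistent with both eyes.  Motion
along the ICP remains ambiguous, and the models in this package are four
rules for resolving that residual ambiguity.

## Coordinate frame and units

Right-handed frame: x rightward, y upward, z increasing away from the
observer.  The fixation point is the origin and lies on the screen plane
z = 0; the nodal points sit at z = −D with D the viewing distance
(default 55 cm) separated by the interpupillary distance i (default
6.5 cm; not part of the study's reported setup, so configurable — the
qualitative model behaviour is robust to it).  All internal quantities
are cm and cm/s; degrees of visual angle are converted at the interface
with the exact tangent relation at distance D.  Velocities and unit-time
displacements are interchangeable (the analysis concerns direction, not
duration).  Perceived directions are reported as spherical angles about
the start point: longitude α, the depth azimuth from the x-axis in the
x–z plane with approaching motion positive (the left/right sign of the
trajectory is folded, matching the mirror-collapsed analysis of the
oblique conditions), and latitude β, the elevation from the x–z plane,
positive upward.

## Stimulus model

A condition is defined by the mean image-line orientation from vertical
(tilt: 0 in the first experiment; 45 or 135 in the second), a signed
orientation disparity Δθ between the two eyes' line images (−6…+6 deg in
2-deg steps), and the sign of the interocular velocity difference
(IOVD).  The line images translate along the axis perpendicular to the
mean orientation with speeds 3.0 ± 0.23 deg/s (left/right eye), i.e. a
fixed IOVD magnitude of 0.46 deg/s, inside a 2.41-deg-radius aperture.
The constraint chain image lines → gradients → planes → ICP is exact
central projection; no small-angle approximation is used in the
geometry.

## The four estimators

**Vector normal (VN).**  The shortest vector from the start point to the
ICP — the 3D analogue of the perpendicular-motion default.  Across an
orientation-disparity sweep its longitudes diverge.

**Cyclopean average (CA).**  The cyclopean image line bisects the two
monocular orientations, and its normal is the common motion axis.  Each
eye's displaced image line crosses that axis at a scalar displacement
|g|²/(g·u) — algebraically identical to that eye's carrier speed — and
the average of the two crossings defines the cyclopean displaced point.
The estimate is the point on the ICP nearest to the ray from the
cyclopean point through that displaced point (the exact intersection
when it exists; otherwise the foot of the common perpendicular on the
ICP).  Because the averaged crossing depends only on the two image
speeds — the constant IOVD — the CA predicts one trajectory for a whole
sweep.  For the vertical-line design this constancy is exact: the
triangulation of the two axis crossings lies on every ICP of the sweep
and on the cyclopean ray.  For oblique tilts the two crossings acquire
unequal vertical components, the back-projected rays become skew, and
the constancy is only approximate (measured spread ≈ 0.15 deg of
longitude across the sweep at tilt 45).

**Bayesian vector normal, single source (BVN1).**  A probabilistic
observer driven by monocular motion alone: the posterior combines a
zero-mean spherical Gaussian slow-motion prior (scale σ0) with Gaussian
likelihoods that penalize the deviation of the velocity from each eye's
constraint plane with a common noise σ.  Because the two planes differ
only through the small eye separation, their combination constrains
depth weakly — a depth offset Δz moves the measurements by roughly
(i/D)·Δz ≈ 0.12·Δz — so already at σ:σ0 of a few percent the posterior
mode shows shorter vectors with longitudes reduced relative to the VN,
while for σ:σ0 → 0 it converges to the VN exactly.

**Bayesian vector normal, two sources (BVN2).**  Adds an independent
dynamic-depth pathway.  Binocular disparity monitored over time yields a
depth displacement for the binocularly matched (cyclopean) feature of
the line — the depth of the CA point, z_CA, which reflects the constant
IOVD.  Its likelihood penalizes the disparity offset (i/D)(v_z − z_CA)
with noise σ_d, while the motion constraints carry σ_m.  Limits: with
σ_d ≪ σ_m the depth pathway dominates and predictions collapse onto a
constant, IOVD-determined trajectory (the CA pattern); with σ_m ≪ σ_d
the motion pathway dominates and the diverging VN pattern returns; with
both noises small and comparable, BVN2 approximates BVN1 because the
depth term's leverage is (i/D)-small.

Both posteriors are positive-definite quadratics in the 3D velocity and
are solved in closed form (3×3 linear systems), batched over conditions
for fitting.  Only noise-to-prior ratios are identifiable, so σ0 is
fixed at 1 and ratios are reported as percentages of it.

**A deliberate design choice.**  BVN1 is *not* the σ_m = σ_d special
case of BVN2: it is the single-source, motion-only model, and BVN2's
depth pathway does not vanish at matched noise.  The alternative — one
model family with BVN1 ≡ BVN2(σ, σ) — cannot simultaneously (a) converge
to the VN in the weak-noise limit, (b) reduce longitudes at σ:σ0 = 4:100,
and (c) leave both noise parameters identifiable from mean response
angles: any likelihood whose constraints are all satisfied by the whole
ICP makes the weak-noise limit the VN for *every* noise ratio and the
motion noise a second-order nuisance, while any point-like depth target
drags the weak-noise limit to the CA point.  The two-pathway structure
adopted here resolves the tension and is what gives the
likelihood-ratio comparison between BVN1 and BVN2 its power.  For model
comparison the single-source model is still treated as nested: the BVN2
fit profiles the boundary σ_d → ∞ (depth pathway off), at which its
predictions coincide with BVN1's exactly, so the likelihood-ratio
statistic is non-negative by construction.

## Response model and fitting

Observed adjustments are longitude/latitude pairs per trial.  The
response model is predicted angles plus iid Gaussian angular noise with
a single unknown variance shared by both angles; concentrating the
variance out reduces maximum likelihood to least squares on the angle
residuals at trial level, and the likelihood-ratio statistic between two
fits to N·ln(RSS1/RSS2) with N the number of scalar residuals.  The
noise ratios are searched on a log scale (bounded Nelder–Mead,
five log-spaced multi-starts plus a depth-pathway-off start; σ_m in
0.1–50% of σ0, σ_d in 0.1–1000% plus the off boundary; ties broken by
lowest RSS then smallest σ_m).  A 41-point log-grid plus bounded scalar
refinement handles the one-parameter fits.

Model comparison uses the likelihood-ratio test with 1 df and the
Schwarz/BIC approximation of the Bayes factor for a one-parameter
difference, BF = exp((χ² − ln n)/2), with n the number of fitted
conditions (14 in both experiments after mirror-collapsing the oblique
design).  This sample-size convention (conditions, not trials)
reproduces every reported χ²→BF pair to within rounding.

Oblique-design trials are mirror-collapsed before fitting: tilt-135
trials map onto tilt 45 with the IOVD sign flipped.  The x-reflection
swaps the eyes — preserving orientation disparity — and both angle
conventions are reflection-invariant, so the collapse relabels
conditions without touching the responses.

Raw probe settings (cyclopean dot position plus horizontal disparity)
are ingested by multiplying disparities by the empirically measured
depth-underestimation factor 0.6, triangulating each dot through the
nodal points, and converting to angles; data already expressed as angles
are assumed pre-scaled.

Uncertainty of the noise estimates is assessed by a within-condition
bootstrap: each replicate resamples every condition's trials with
replacement (preserving design balance) and refits BVN2, warm-started at
the point estimate with a multi-start fallback; replicates whose fit
fails are dropped and more than 5% dropped is an error.  Across
observers, the motion-minus-depth noise difference is tested with a
two-tailed one-sample t test (df = observers − 1).

## Synthetic data

The generator reproduces the two stimulus designs exactly (14 vertical
and 28 oblique conditions at the study's speeds, IOVD and aperture) and
simulates observers as BVN responders plus iid Gaussian angular response
noise, default SD 3 deg — chosen as a plausible adjustment-task
precision, since per-trial variability is not reported — with 20
repetitions per condition.  Each condition draws from a substream
derived from the master seed by hashing the condition key, so extending
a design never perturbs existing draws.  What the generator does *not*
emulate: adjustment dynamics and training effects, response biases
(anchoring, compression) unrelated to the model, lapses, and any
deviation of real observers from the model family itself.  Passing
recovery tests therefore demonstrates that the pipeline is
self-consistent and statistically powered at realistic noise levels, not
that real data are this clean; real-data likelihood ratios are far
smaller than synthetic ones because human responses violate the model in
ways response noise does not capture.

## Recovery study

The recovery protocol simulates observers over the full study design
(both experiments, 42 conditions, 20 reps, 3 deg response noise): an
alternative cohort generated by BVN2 at σ_m:σ_d:σ0 = 4:2:100 and a null
cohort generated by the single-source model at 3:100.  At 100 observers
per arm the median relative recovery error is ≈ 12% for σ_m and ≈ 5% for
σ_d, the two-source model is preferred (BF > 3) in 100% of alternative
datasets, and falsely preferred in 0% of null datasets.  Motion noise is
recovered less precisely than depth noise because its first-order effect
on mean angles is damped by the strong leverage of the motion
constraints; its information enters mainly through latitude shrinkage.

## Numerical notes

* Degenerate inputs raise typed errors: projection rays parallel to the
  screen, parallel constraint planes (an unresolvable stimulus), a
  cyclopean ray parallel to the ICP, fully ambiguous (tangential)
  gradients, probe disparities implying points behind the eyes.
* The ICP anchor is the minimum-norm point satisfying both plane
  equations, so the vector normal is immediate and anchor-independent.
* Constraint-plane normals recovered from an ICP are co-oriented
  (positive mutual dot product) before use in the posterior.
* Angles are serialized to 6 decimal places in CSV artifacts, which caps
  file round-trip fidelity at 5·10⁻⁷ deg — far beyond measurement
  precision.
* Problem sizes of the shipped scripts (bootstrap B = 400; recovery 40
  observers per cohort by default, 100 in the acceptance suite) were
  chosen to make each driver a few minutes on one core; all are
  parameters.

## Known limitations

* The likelihood linearizes nothing, but the depth pathway's target
  (z of the CA point) is a modelling idealization of feature tracking;
  alternatives (e.g. oriented-disparity receptive-field inputs) are out
  of scope.
* Heavy-tailed slow-motion priors (lognormal, Laplace, Cauchy) are not
  implemented; the spherical Gaussian keeps the posterior closed-form.
* Perceived speed is not modelled; only direction enters the likelihood.
* Hierarchical (multi-observer) estimation is out of scope; observers
  are fitted independently and compared with frequentist summaries.
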