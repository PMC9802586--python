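# Methods

This note documents the models, parameter choices and numerical decisions in
`fatvt`, in the spirit of a methods appendix: what is simulated, what the
synthetic data do and do not emulate, and where design latitude was resolved
by explicit choice.

## Imaging model and segmentation

The left ventricle is idealized as a half-ellipsoidal shell (defaults: 80 mm
base-to-apex, 60 mm outer basal diameter, 10 mm wall) voxelized at 1 mm.
This is a deliberate desk-scale stand-in for patient anatomy: no right
ventricle, papillary muscles, or wall-thickness variation.

CT-like volumes place infiltrating adipose tissue (inFAT) as hypoattenuation
between −180 and −5 HU, split at −50 HU into dense inFAT and fat–myocardium
admixture; non-injured myocardium is drawn N(40, 15) HU clipped positive
(only the fat range is physiologically constrained; any positive band
works). LGE-like volumes use the full-width-half-maximum convention:
intensities above 50% of the in-mask maximum are dense scar and 35–50% gray
zone. Boundary behaviour is fixed as: exactly −50 HU → dense fat; exactly
50% or 35% of max → gray zone (ties resolve toward the less-remodeled class
at the dense boundary). Artifact-flagged voxels are treated as non-injured.
Masses use 1.055 g/cm³. The published ablation-lesion radii/volumes
(4.56 mm/397 mm³, 3.07/121, 2.50/66) are reproduced as full-sphere volumes;
note (4/3)π·2.50³ = 65.4 mm³, 0.8% below the printed 66 — consistent with
rounding of the published radius — so checks carry 1 mm³ slack. Lesions in
dense inFAT and admixture reuse the dense-scar and gray-zone radii.

Lesions are superellipsoidal blobs (exponent 2.5, semi-axes 6–14 mm) with
dense cores and heterogeneous rims, allocated across seven anatomical
segments with apex/inferior-heavy weights; fat lesions overlap scar
according to per-segment overlap fractions (defaults replicate the reported
ranking: apex and inferior high, basal septum low — the exact probabilities
are calibration choices, not ground truth). Voxel intensities are drawn
strictly inside the band of their planted class and lightly smoothed
(Gaussian, σ = 0.4 voxel), so segmentation recovers the planted truth to
≥99% with discrepancies confined to lesion boundaries.

## Universal ventricular coordinates and substrate merge

Transmural depth is the normalized Euclidean distance between endocardial
and epicardial surfaces (distance transforms); apicobasal position is the
normalized polar angle of the ellipsoid-scaled direction (0 apex, 1 base);
rotational angle runs counterclockwise from the lateral wall, periodic in
360°. The cited patient-mesh UVC algorithm is replaced by this
analytic-shell equivalent, which is exactly testable. Sector boundaries are
config constants with the septum spanning 60–180°. Tag transfer between
grids is nearest-neighbour in UVC space with the rotational axis embedded on
a circle (full turn ≡ 2.0 units against the unit apicobasal/transmural
spans).

The hybrid merge maps the 3×3 CT×MRI label pairs onto seven classes; the two
combinations the source taxonomy leaves open (dense fat + gray zone,
admixture + dense scar) resolve by dense dominance — the insulating
component governs electrophysiology — with the heterogeneous partner
retained for composition accounting. Overlap regions at a point use spheres
(not surface discs) of 1 cm with a 10% volume-fraction threshold, to count
intramural remodeling.

## Electrophysiology

Membrane kinetics are the ten Tusscher–Panfilov (2006) human ventricular
model, epicardial variant everywhere (no transmural cell heterogeneity;
config-exposed). The published initial state is relaxed through 10 s of
quiescence before use (the slow intracellular Na+/K+ pools make the raw
initial conditions drift ~0.1 mV per 10 s); the relaxed state is cached and
drifts < 0.1 mV over 10 s. Integration is operator splitting: Rush–Larsen gates and
forward-Euler concentrations/voltage at dt ≤ 25 µs, then explicit diffusion
on the conducting-voxel graph with harmonic-mean face diffusivities (no-flux
boundaries and insulators fall out of missing edges). Conductivities
(S/m → mm²/ms via β·Cm = 1400 F/m³): healthy 0.08/0.00889
longitudinal/transverse; gray zone and admixture share the border-zone
parameterization (transverse ×0.1; INa, ICaL, IKr, IKs conductances ×0.38,
0.31, 0.30, 0.20); fibrofatty tissue halves both conductivities again;
dense classes do not conduct. A lookup-table variant of the ionic update
(voltage-gridded steady states, Rush–Larsen decay factors and current
coefficients at 0.02 mV) drives the tissue solver ~4–5× faster; it matches
the exact update to <0.1 ms upstroke timing, <1 mV peak and ~2–3% APD90.

Peak-current scaling is verified under action-potential clamp: clamped to
the baseline paced waveform, the border-zone gNa factor reduces peak INa by
62.0%, matching the configured factor. In a free-running paced cell the
apparent reduction is smaller (~53%) because the slower upstroke lets INa
activation recover — the clamp protocol is the standard way these
experimental percentages are defined.

The diffusion tensor is diagonalized per axis (D_aa = D_t + (D_l−D_t)f_a²):
exact for the axis-aligned fibers used in 1D/2D work, an orthotropic
approximation on shells. At the 0.5 mm desk grids the *transverse*
conductivity sits below the discrete propagation limit (its space constant
is a fraction of a voxel), which would decouple 2D sheets into 1D strands;
2D phantoms therefore use isotropic coupling at each tissue's longitudinal
conductivity, stated wherever it applies. The dt stability bound is checked
and refining dx requires refining dt (the solver raises otherwise).

On a 1D strand at dx = 0.05 mm, dt = 12.5 µs (converged to <0.1% against
half steps) the fibrofatty vs admixture conduction-velocity decrease is
29.9%. Continuous cable theory gives 1 − √0.5 = 29.3% for a 50% conductivity
reduction; the figure of ~25% quoted for this parameterization is therefore
an estimate on the low side, and the package reports the simulated value.

## VT induction, detection and circuits

Programmed stimulation delivers an S1 train (default 6 × 450 ms) to ~1 mm³
of tissue, then up to four premature stimuli; the first starts at a 350 ms
coupling and decrements by 10 ms until capture fails (ERP), each subsequent
level starting 20 ms above the previous ERP (the published protocol does not
print coupling intervals; these are explicit, config-exposed choices, as are
stimulus strength −80 A/F × 2 ms and the 50 ms capture window). Sites in
non-conducting tissue shift automatically to the nearest conducting voxel.
A checkpoint/restore scheme simulates the S1 train once per site.
Desk-scale tests and drivers use reduced schedules (2 × 400 ms S1, coarser
decrements, 1–2 premature levels) chosen as problem sizes, with the full
defaults available.

Re-entry is "induced" when some node re-activates at least twice after the
last stimulus (beyond a transit allowance for the directly paced wave;
slow-corridor substrates need a longer allowance, exposed on the protocol)
with inter-activation periods stable to 25% CoV. The critical site is the
node with the most repeated activations — an automated stand-in for manual
exit-site selection, with coordinate override available. Circuit windows
span ±0.2 apicobasal and ±36° rotational around the exit, full transmural;
the cycle's activation is cut into eight equal isochrones mapping to exit
(1), outer loop (2–3), entrance (4), common pathway (5–8) and critical
isthmus (6–7). Isochrone edge ties fall to the lower bin and the final bin
is closed.

The 2D "channel" phantom is the canonical isthmus: a slow fibrofatty
corridor (8 mm wide, flared mouths) crossing a 20 mm dense wall on a 70 mm
sheet, with a second, healthy gap through the wall that closes the
re-entrant loop (the role the surrounding ventricular wall plays in 3D). A
premature beat blocks antegradely in the corridor, conducts through the
healthy gap, re-enters the corridor retrogradely, and sustains with a
~550 ms cycle because the slow transit keeps the loop period above the
refractory period. Geometry constants were chosen from the loop-period
arithmetic (corridor transit + return path vs ERP ≈ 300 ms) and verified by
simulation; narrower or shorter corridors fail at the exit (source–sink
mismatch) or re-block, which is physiologically faithful.

## Synthetic EAM data and DZ calibration

Mapping points scatter around the endocardial surface with ~1.5 mm
off-surface jitter (projection/filtering then behaves like the clinical
pipeline; the interactive rigid pre-alignment of real EAM export is out of
scope — synthetic data live in a common frame). Activation times come from
a graph fast-marching front seeded at the basal septum, mildly slowed
(×0.8) where fat is present. Per-region bipolar/unipolar voltages use the
reported means and SDs; BiV/UniV are capped at 1.5/8.3 mV downstream, with
LVZ cutoffs 0.5/3.3 mV. Ablation flags land preferentially on low-voltage
points.

Deceleration zones are *measured*, not assigned: a point is a DZ when ≥5 of
8 isochrones fall within 1 cm of it (graph-geodesic neighbourhoods). To make
the measured per-region DZ odds land on the configured targets (1.69, 1.42,
0.45, 0.83 for inFAT_inScar, inFAT_noScar, Scar_noFat, none, each versus
the rest; pooled prevalence anchor 0.35), the generator plants "slow sites"
whose rank-spread delay ramps guarantee crowding at the site, with
per-point planting rates solved so that P(site within 1 cm of a point)
matches its region's target (an iterative log-space fit — regions
interleave at the 1-cm scale, so this is genuinely per-point). Site counts
are pinned at their expected values per region (quasi-random rounding,
purity-weighted placement, minimum 10 mm separation) to tame the variance
of spatially clustered flags, and each site is verified to register as a DZ
under the actual crowding measurement, strengthening its ramp if the global
binning swallowed it. Residual planting-to-measurement dilution from region
mixing is absorbed by small per-region rate deltas estimated once from
pilot cohorts. Over held-out seeds the pooled 20-heart inFAT_inScar odds
ratio distributes as ≈1.70 ± 0.14; the spread is intrinsic — DZ flags are
correlated over ~1.5 cm patches, so a 20-heart cohort offers only a few
hundred independent structure draws.

Cohort masses use a Gaussian copula with lognormal margins (means/SDs
19.0/13.0 and 26.3/14.2 g); the latent correlation is solved in closed form
so the *observed* Pearson correlation equals 0.639. VT counts are Poisson
with log-rate a + b·fat + c·scar, b = ln(1.10)/5.55 per gram, c = ln(1.0),
and the intercept anchoring an average heart at 5.8 expected VTs (the
hybrid-model mean).

## What the synthetic data do not emulate

No torso/CT physics, contrast kinetics or scanner noise; no right ventricle
or papillary anatomy; no patient-to-patient shell geometry variation; EAM
noise is Gaussian and spatially white; activation fronts are eikonal-style,
not full EP, by design (the EAM analysis must be testable independently of
the simulator). Passing tests therefore demonstrate that the *pipeline*
recovers planted structure under its stated assumptions — not that the
clinical effect sizes would be recovered from real patients.

## Problem sizes

Defaults used by the tests and the reproduction script: 1 mm image voxels
(~340k-voxel grids), 600–800 EAM points per heart, 20-heart pooled EAM
cohorts, n = 2,000–5,000 statistical cohorts, 1D strands at 0.05 mm, 2D
phantoms at 0.5 mm (≈10–20k nodes), coarse shells for suite orchestration.
These sizes were chosen so the full chain runs on a single CPU core in
minutes while every recovered quantity stays within its sampling error of
the calibration target.
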