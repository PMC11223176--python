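# Methods

This note documents the models, the synthetic study conditions, and the
numerical choices behind `renalperf`.

## Regional partitioning

**TLCO.**  The parenchyma is divided into 12 concentric layers of equal
normalized thickness.  For each mask pixel P the fraction f = r/R(θ) is
computed, where r = |P − C| is the distance to the mask centroid C and
R(θ) the distance from C to the mask boundary along the same ray.  The
layer counted from the inside is min(12, ⌊12·f⌋ + 1), then relabeled so
layer 1 is outermost and layer 12 innermost.  R(θ) is obtained by
ray-marching the binary mask at 0.1 px resolution (vectorized over all
pixels); a ray terminates at its first exit beyond the pixel's own radius,
which guarantees f ≤ 1 even for mildly non-star-convex masks.  When the
centroid falls outside the mask (strongly bean-shaped kidneys), the pixel
of maximal interior distance-transform value is used instead and a warning
is recorded.  Aggregates follow the standard definitions — cortex = layers
1–3, medulla = layers 8–10, whole kidney = all 12 — computed as
pixel-weighted means over the constituent layers by default; unweighted
layer-of-layer means are available (`layer_weighted=True`) because either
reading of "mean of the three outer layers" is defensible and the two
differ when layer areas are unequal.

**TEO.**  The pole axis is the principal axis of the pixel coordinates,
oriented by the mask's caudal-pole hint (or −y by convention).  Each
pixel's angle φ ∈ [0°, 180°] to the caudal direction (folded across the
long axis via arccos) gives segment min(10, ⌊10·φ/180⌋ + 1): segment 1
caps the caudal pole, 10 the cranial pole.  Bins are half-open with exact
edges assigned to the higher-numbered segment (φ = 90° → segment 6).  An
unfolded 360° sweep is available (`folded=False`); whether the original
scheme folds the two lateral sides is not determinable from published
descriptions, and folding is the only way ten pole-to-pole segments cover
the kidney.  Nearly circular masks (principal-axis eigenvalue ratio
≤ 1.05) without a hint raise an ambiguous-axis error.

## BOLD R2*

Mono-exponential magnitude decay S(TE) = S0·e^(−R2*·TE) over 12 echoes
(4.2–50.4 ms, ΔTE = 4.2 ms).  The default estimator is weighted least
squares on ln S with weights S², solved voxelwise from the 2×2 normal
equations; it is exact on noiseless data and fast enough for whole
cohorts.  The nonlinear estimator refines this solution with a
trust-region least-squares fit of the raw model and is preferred at low
SNR, where log-domain weighting is biased.  Echoes below an optional noise
floor (conventionally 3× the background SD) are excluded per voxel to
limit Rician bias at long TE; voxels with fewer than 3 usable echoes are
marked invalid (NaN), and negative R2* estimates are clipped to zero with
a per-voxel flag.  A noise-floor offset term in the model (an additive
constant) is deliberately not fitted: with 12 magnitude echoes it trades
bias for variance and the reference estimator for this acquisition is not
public.

## ASL RBF

Single-compartment pulsed-ASL (QUIPSS-II form):
RBF = 6000·λ·ΔM / (2·α·M0·τ·e^(−TI/T1b)) in mL/100 g/min, with defaults
λ = 0.9 mL/g, α = 1.0 (adiabatic FAIR inversion), τ = 1.0 s, TI = 2.0 s,
T1b = 1.65 s at 3 T; all constants are config-exposed.  The acquisition's
"TI1 2000 ms, bolus length 1000 ms" maps to TI = 2.0 s, τ = 1.0 s.  Two
consecutive runs are quantified separately and averaged afterwards —
equivalent to averaging first when M0 is shared, but retaining per-run
diagnostics.  Voxels with M0 ≤ 0 are flagged invalid, never divided
through.  Because scanner inline quantification pipelines are proprietary,
the absolute RBF scale is defined by this documented model.

## DCE pharmacokinetics

Signal is converted to concentration either as relative enhancement
C ∝ (S − S̄0)/S̄0 or by exact inversion of the spoiled-gradient-echo signal
equation (defaults T10 = 1.4 s, r1 = 3.6 /mM/s, TR = 4.8 ms, flip 17°).
The arterial input is a gamma-variate bolus with a dispersed recirculation
shoulder; aortic ROI placements map to (delay, dispersion) pairs —
Cr25 (0 s, 0 s), Cr12 (0.5, 0.5), Ca (1.0, 1.0), AD (1.5, 2.0) — since
anatomy fixes only the geometry, not the signal consequence.  Placement is
applied as a grid-interpolated shift plus convolution with a normalized
exponential kernel.

The two-compartment models follow the standard renal forms.  Plasma:
v_p·dc_p/dt = F_p·c_a − (F_p + F_t)·c_p.  Uptake (C2UM) traps filtrate,
dC_u/dt = F_t·c_p; filtration (C2FM) drains it through a tubular
compartment v_t·dc_t/dt = F_t·(c_p − c_t) with mean transit time
T_t = v_t/F_t.  Tissue curves are rectangle-rule discrete convolutions of
the AIF with the closed-form impulse responses (the degenerate T_p ≈ T_t
case uses the t·e^(−t/T_p) limit); simulator and fit share the operator,
so noiseless round trips are exact to optimizer tolerance.  Note the
uptake model is the T_t → ∞ limit of the filtration model, so a C2FM fit
on uptake-like data correctly runs to a very long fitted T_t.

Estimators: **MS** divides the maximum 3-point-smoothed slope of the
tissue curve by the AIF peak.  **MF** solves the discrete deconvolution by
Tikhonov regularization via SVD; the regularization weight is chosen by
generalized cross-validation (GCV) by default — the L-curve corner, also
provided, occasionally degenerates to a near-zero weight on bolus-shaped
noisy curves and produces unbounded flow spikes, while GCV stays stable on
both noiseless and noisy inputs; truncated SVD is a further option.  F_p
is the IRF maximum (a late-time plateau statistic is exposed for
uptake-dominated tissues).  **C2UM/C2FM** use trust-region least squares
on log-transformed parameters with 5 multi-starts from log-spaced plasma
transit times (2–40 s), initialized from the MS flow.  Non-convergence
returns a flagged result, never a silent number.  RBF = F_p/((1−Hct)·ρ)
with Hct = 0.45 and ρ = 1.05 g/mL.  No bolus-arrival re-alignment is
applied by default: fits use the supplied AIF as-is, which keeps the
noiseless round trip exact and leaves AIF-placement bias — a real and
deliberately reproducible phenomenon (MS and MF flows grow monotonically
with added delay/dispersion) — observable.

## CEUS TIC parameters

From the raw samples of a 90 s recording: baseline = mean of the pre-rise
window; PI = max − baseline with peak ties broken to the earliest sample;
WiR = OLS slope of pre-peak samples whose baseline-subtracted intensity
lies in [0.10·PI, 0.85·PI]; WoR = OLS slope of post-peak samples in
[0.40·PI, 0.85·PI]; TI and TO are the x-intercepts of those lines at the
baseline level; TTP is the peak time from injection; RT = TTP − TI,
FT = TO − TTP; AUC is the trapezoidal integral of the baseline-subtracted
curve from TI to TO with interpolated endpoints.  "10% above baseline" is
read as 10% of peak enhancement — the fraction-of-peak convention pairing
naturally with the 85% bound; the literal 1.10× baseline reading is an
option (`wir_band_mode`).  Band edges are inclusive within 1e-12 so exact
grid hits are retained.  An empty regression band flags the parameter set
invalid rather than producing zeros, and a TO beyond the record is
extrapolated with a flag.  Optional 3-sample pre-smoothing (off by
default) is available for noisy clinical curves; intensities are assumed
already linearized by the exporting software.

## Statistics

Spearman correlations use tie-corrected ranks with the t-approximation for
n ≥ 10 and exact permutation enumeration below that (tie-free case).
Interpretation bands on |r|: negligible < 0.10, weak [0.10, 0.40),
moderate [0.40, 0.70), strong [0.70, 0.90), very strong ≥ 0.90; boundary
values go to the higher band.  Bonferroni m is always the size of the
requested batch, never hard-coded.  Treatment effects are random-intercept
linear mixed models fit by maximum likelihood (statsmodels MixedLM with
variance components implementing dog / side-within-dog /
segment-within-side nesting as applicable); significance is a likelihood
ratio test against the model without treatment, referenced to χ²(1).
Singular or failed fits fall back to reduced nesting with a warning
record; boundary (zero-variance) solutions are retained and flagged.
Calibration on 8-subject null cohorts puts the empirical type-I error
near the nominal 0.05 (checked in the test suite over 1000 simulated null
cohorts).

## Synthetic study conditions

The phantom cohort emulates the crossover design: 8 subjects × 2
treatments × 2 kidneys (one mid-coronal slice each).  Masks are
superellipses with an optional hilar notch, jittered per subject/side;
the caudal pole points to −y.  Ground-truth maps follow the TLCO layering:
layers 1–3 carry the cortical value, 8–12 the medullary value, 4–7 a
linear cortico-medullary transition.  The default regional truths are the
published canine TLCO means (saline / dopamine): cortical RBF
338.72 / 409.87, medullary RBF 156.63 / 177.46 mL/100 g/min; cortical R2*
28.58 / 27.86, medullary R2* 20.77 / 17.94 1/s — so dopamine raises RBF
and lowers R2* by construction, with the regional deltas of the reference
table built in.

Biological variability is latent and multiplicative on RBF / additive on
R2*: a subject factor (CV 0.15 on RBF; SD 2.0 1/s on R2*) with correlation
−0.7 between the two — chosen once to emulate the moderate inverse
perfusion–oxygenation coupling seen at baseline — plus smaller side
(CV 0.05 / SD 0.5) and visit (CV 0.04 / SD 0.8) factors.  Measurement
noise: Rician for all MRI magnitude data (Gaussian SD on the real and
imaginary channels before the magnitude; BOLD SD 15 a.u. at S0 = 1000,
ASL SD 5 a.u. at M0 = 1000), Gaussian SD 0.02 mM on DCE concentration
curves, and multiplicative Gaussian noise with CV 0.15 on CEUS intensity.
DCE truth uses the filtration model with F_p = 134 (control) vs 161.5
(dopamine) mL/min/100 mL — the ratio of the whole-kidney reference RBFs —
with v_p = 30 mL/100 mL, F_t = 30 mL/min/100 mL and T_t = 60 s held fixed
across treatments (dopamine increases flow without changing filtration).
CEUS bolus defaults (cortex: baseline 5, amplitude 20 a.u., onset 8 s,
rise 10 s; medulla smaller and slower) are plausible rather than
calibrated, since no bolus-shape statistics are published for this
population; the dopamine amplitude factor is a modest ×1.10, below the
detection limit at CV 0.15 — consistent with CEUS's known variability.

Per-dataset random streams are spawned from one master seed via
`numpy.random.SeedSequence(master_seed, spawn_key=...)`, so cohorts are
bit-reproducible and streams are independent across subjects, treatments,
sides and modalities.

What the phantom does **not** emulate: k-space acquisition and
reconstruction artifacts, B0/B1 inhomogeneity, respiratory motion,
partial-volume mixing at layer boundaries, microbubble destruction, or
attenuation.  Passing tests therefore demonstrate the correctness of the
quantification chain under its stated models, not robustness to those
real-data effects.

## Problem sizes and numerics

Default grids: 96×96 masks (~1200–1500 parenchymal pixels), 12 echoes,
2 ASL runs, 80 DCE frames at 1.5 s, 181 CEUS samples at 0.5 s.  The
statistical calibration checks use 1000 simulated null cohorts and 200
effect-recovery cohorts of 8 dogs × 2 sides; the end-to-end direction
check uses 100 ASL+BOLD cohorts.  These sizes make the full suite and the
acceptance script reproducible on a single CPU in a few minutes while
keeping every estimator at its intended operating point.  Optimizer
tolerances: C2 fits xtol 1e-10/ftol 1e-12 with parameters log-transformed
for positivity; deconvolution uses a 60-point log-spaced λ grid over
[1e-6, 1]·σ_max; TLCO ray marching at 0.1 px.

## Known limitations

* ROI-level DCE only (matching whole-kidney ROI practice); no voxelwise
  PK maps.
* Single-slice 2D analysis; no 3D TLCO.
* The C2UM fit on filtration-generated tissue is intentionally
  misspecified and recovers flow only approximately (within ~10% at the
  default truth); model selection is left to the user.
* The absolute ASL scale matches the package's documented model, not any
  vendor's inline implementation.
* CEUS parameters are semi-quantitative; the generator's bolus shape is a
  design choice, not a calibration.
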