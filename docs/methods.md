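# Methods

This note documents the models, numerical choices and limitations behind
`gaitwrench`, in the spirit of a model-description appendix. Conventions used
throughout: right-handed lab frame with X anterior, Y vertical (up), Z to the
subject's right; forces in body-weight units (BW = mass × g, g = 9.81 m/s²);
moments in Nm/kg; gait cycles resampled to 101 points from heel strike to
ipsilateral heel strike; stance fraction = (toe off − heel strike) / cycle
duration.

## Data model and normalization

A `GaitTrial` holds uniformly sampled, synchronized channels: joint angles
(rad), optional segment positions/orientations (m, rad), per-foot GRF (BW)
and GRM about the lab origin (Nm/kg), optional COP paths and COM
acceleration, plus gait events. Invariants are enforced by `validate()`:
strictly increasing uniform time, alternating heel-strike/toe-off events per
side, and forces exactly zero outside stance intervals (a stance may be
clipped by the trial boundary).

Gait events are detected by threshold crossing of the vertical GRF with
linear interpolation of the crossing time. The default threshold is 20 N, a
common force-plate convention; events may equally be supplied externally.
Time normalization interpolates every channel onto 101 equally spaced points;
the default interpolant is piecewise-linear (exact on already-normalized
input, error ≈ h²ω²/8 for a sinusoid of angular frequency ω at sampling step
h), a cubic interpolant is available behind the `kind="cubic"` flag.

Subject scaling is anthropometric-table based: the bundled Winter (2009)
full-body fractions give segment mass = fraction × body mass and segment
length = fraction × stature, with COM and radius-of-gyration fractions passed
through. Mass fractions sum to one, so total mass is conserved exactly.
Marker-based scaling from static trials is deliberately out of scope; the
package's input boundary is kinematics, not marker clouds.

## Synthetic cohort generator

The generator emulates the study conditions of a slow-walking knee-OA
cohort: 18 subjects, ~99 cycles each, mass 80.5 ± 15.3 kg, height
1.65 ± 0.12 m, self-selected speed 0.75 ± 0.23 m/s (all truncated at ±3 sd;
speed floored at 0.2 m/s). Cycle duration is 1.4 · (0.75/v)^0.3 s, stance
fraction 0.60, sampling 100 Hz.

Deterministic templates: the vertical GRF is a double Gaussian hump (peaks
near 25 % and 75 % of stance) under a smooth taper, scaled so that after
normalization the humps land near 1.1 BW; the anterior-posterior force is a
braking/propulsion S-curve scaled by √(v/0.75); the medio-lateral force is a
small half-sine of opposite sign per foot. Joint angles are low-order
Fourier/Gaussian templates with speed-scaled amplitudes, and a forward
kinematic chain (hip → knee → ankle → foot, driven by those angles) provides
the segment position and orientation channels that inverse dynamics needs.

Structure, by construction:

- **Shared low-rank variability.** A fixed bank of smooth latent modes (rank
  5 by default, amplitudes 0.06·0.75^k BW tapering geometrically) perturbs
  the force *and* the angle channels with the same latent draw z. This is the
  regime in which conditioning forces on kinematics is consistent, made
  explicit and controllable rather than assumed.
- **Subject effects.** Each subject carries a random smooth template offset
  (3 harmonics; 0.03 BW on forces, 0.02 rad on angles), independent between
  the kinematic and force groups, so a model cannot learn a new subject's
  force offset from their kinematics — leave-one-subject-out validation is
  strictly harder than leave-cycles-out, as it is in practice.
- **Exact bookkeeping.** The vertical force is linearly projected (by
  subtracting a multiple of the template, which vanishes outside stance) so
  the whole-cycle mean of both feet is exactly 1 BW; the map from latent
  variables to waveforms stays linear, so with noise off the stacked
  waveforms have numerical rank equal to the latent rank.
- **Invertible moments.** The COP path progresses heel-to-toe (smoothstep,
  18 cm) from a plant anchored to the *nominal* stance-ankle position of the
  template kinematics; GRM about the lab origin is computed exactly as
  g·(r × F). ZMP inversion therefore recovers the generating COP to machine
  precision, and COM acceleration is set to g·F_total + g⃗ so the whole-body
  wrench identity holds exactly.
- Measurement noise is white (0.02 BW tapered to zero at stance edges;
  0.01 rad on angles).

What the generator does **not** emulate: soft-tissue artefact, sensor drift,
non-stationary gait, speed variation within a subject, asymmetric pathology,
and any nonlinearity between kinematics and kinetics. Passing tests on this
cohort therefore demonstrates correctness of the machinery and achievable
accuracy *when the low-rank assumption holds*, not clinical accuracy.

## PPCA estimator

Features: per cycle, all joint-angle channels (101 points each), the stance
fraction as a scalar timing feature, and the six per-foot GRFM channels.
Channels are standardized by one pooled-SD scale per channel (stored in the
model) so radian, BW and Nm/kg channels are commensurable; a numerically
constant channel receives a unit-order scale so float jitter is not
amplified. Whole-body wrench features from COM acceleration can be appended
to the observed block behind a layout flag.

Fitting is the closed-form maximum-likelihood solution via
eigendecomposition (an EM iteration is kept in the test suite as an
independent cross-check, converging to the same covariance). In the usual
n < D waveform regime the n × n Gram matrix is decomposed instead; σ² is the
mean of the discarded eigenvalues, averaged over the min(n−1, D) − q nonzero
ones when the spectrum is rank-deficient. The default component count is the
smallest q explaining 95 % of variance, overridable.

Inference is exact Gaussian conditioning through the latent posterior:
with M = W_oᵀW_o + σ²I (q × q), the conditional mean is
μ_t + W_t M⁻¹ W_oᵀ (x_o − μ_o) and the conditional covariance diagonal is
σ²(1 + diag(W_t M⁻¹ W_tᵀ)); at σ² = 0 the posterior uses the pseudo-inverse.
Both equal dense conditioning with C = WWᵀ + σ²I by the push-through
identity, which the tests verify on random instances to 1e-9. Predictions
are de-standardized, reshaped to waveforms, and masked to zero outside the
stance window implied by the stance-fraction input. Double-support
indeterminacy is handled by predicting per-foot GRFM directly, with the
stance-timing feature informing the conditional; no explicit force-sharing
rule is applied.

Cross-validation: leave-one-subject-out refits the model (including
standardization scales) per fold; the leave-cycles-out counterpart is a
seeded grouped K-fold over cycles with all subjects represented in training.
Scores are per-cycle RMSE and R² per channel, reported as mean ± sd — R² is
the coefficient of determination about the reference mean, not squared
Pearson correlation.

## ZMP centre of pressure

With the wrench about the lab origin and the COP on the ground plane y = 0,
M = r × F gives x_ap = M_z/F_y and z_ml = −M_x/F_y (worked example:
F = (0, 700, 0) N, M = (−35, 0, 70) Nm → COP (0.10, 0.05) m). Samples with
F_y below 20 N are flagged undefined rather than evaluated. Because the
ratio degenerates as F_y → 0, the first and last 15 % of stance are
replaced: per coordinate, a degree-10 polynomial (Chebyshev basis on the
[−1, 1]-mapped stance axis, for conditioning) is fitted by least squares to
the valid 15–85 % core, with the calcaneus origin enforced as an *equality
constraint* at 0 % and 100 % of stance (solved as a KKT system — a hard
constraint, rather than a large finite weight, so the anchor holds to
machine precision). The fitted branch is linearly blended into the raw
junction value over a 2 % window inside each end region, so the output is
continuous at 15 %/85 % and the core samples are never modified. Fewer than
12 valid core samples is an error (underdetermined fit). Invalid samples
inside the core, if any, are filled from the fit and flagged.

## Inverse dynamics

The whole-body wrench is F = m(a_com − g⃗), returned in BW; its moment
channel is zero (whole-body angular momentum is not tracked).

Knee moments use a two-segment (foot, shank) bottom-up Newton–Euler
recursion — the external knee moment depends only on the distal free body,
so thigh and pelvis dynamics are unnecessary. Segment inertia is the
isotropic radius-of-gyration model I = m(k·L)²; segment angular velocity is
the time derivative of the orientation-angle channels (exact for planar
motion, first-order in the small out-of-plane angles); accelerations use a
5-point central finite-difference stencil with second-order one-sided
endpoints (endpoint samples can show small artefacts on kinked templates).
The ground wrench must be expressed at the COP; its moment channel is
treated as the free moment. The reported external moment is the moment of
the ground wrench about the knee joint centre (equivalently minus the
inter-segmental reaction moment), resolved in the shank anatomical frame
R = R_z(r_z)·R_x(r_x)·R_y(r_y): flexion positive about +Z′, adduction
positive into varus (+X′ right side, −X′ left), internal rotation positive
(−Y′ right, +Y′ left). The implementation is verified against an
independent system-level moment balance (combined foot+shank free body taken
directly about the knee) to 1e-8 Nm.

Wrench transport follows M′ = M + (p − p′) × F and round-trips to 1e-12.

## Loading metrics and statistics

- RMSE and R² (coefficient of determination about the reference mean; a
  zero-variance reference yields NaN, flagged). Values are computed per
  cycle and summarized mean ± sd.
- First/second peak: local maxima inside the 0–50 % and 50–100 % stance
  half-windows; if a half-window has no local maximum its global maximum is
  used and a fallback flag is set (auditable on monotone curves). Impulse:
  trapezoidal time integral over stance (value·s); forces vanish in swing so
  the stance restriction is numerically immaterial for forces and a stated
  choice for moments.
- Wilcoxon signed-rank: zero differences dropped (Wilcoxon's convention),
  ties mid-ranked; for n ≤ 25 the two-sided p is exact — the W⁺
  distribution over all 2ⁿ sign assignments is built by integer convolution
  of the doubled mid-ranks, equivalent to full enumeration —
  p = min(1, 2·min(P(W⁺≤w), P(W⁺≥w))); above n = 25 a normal approximation
  with continuity and tie correction is used.
- Benjamini–Hochberg step-up at q ≤ 0.05; q-values are the monotone-adjusted
  p·m/rank. Normality screening (e.g. Shapiro–Wilk) is presumed done by the
  analyst choosing the nonparametric test and is not implemented.
- `compare_workflows` pairs two workflows' per-cycle features, reports MAD,
  RMSE, R², exact Wilcoxon p and BH q per (component × feature) cell;
  identical columns are reported with p = 1 (no evidence of difference)
  rather than as a degenerate test.

## Pipeline, proxy contact force, and I/O

Per cycle the pipeline runs: normalize → PPCA inference → ZMP + repair
(calcaneus anchor from configuration, or from the ankle channel at heel
strike minus 5 cm if unset) → knee moments → optional contact-force proxy.
Outputs are OpenSim-dialect STO tables with provenance headers (package
version, config hash, model hash); runs are bit-deterministic given inputs.

The contact-force proxy is a static frontal-plane balance about two condylar
contact points separated by the intercondylar distance d (default 0.045 m, a
common literature value): medial − lateral = 2·KAM/(d·g) in BW and
medial + lateral = axial load; a negative compartment is clamped to zero
with the other side taking the whole load, flagged per sample. It ignores
muscle co-contraction (which roughly doubles real compartment loads) and is
suffixed `_proxy` in every output; it exists so the pipeline has an
end-to-end demonstration without an external musculoskeletal contact solver,
whose 12-DOF knee, ligament and cartilage models are explicitly out of
scope.

File formats: STO/MOT ASCII (key=value header, nRows/nColumns validated,
tab-separated body, mandatory leading `time` column; angles written in
degrees with `inDegrees=yes` per OpenSim convention, held internally in
radians), TRC marker files (read-only), and a CSV trial dialect with a YAML
sidecar declaring units, body weight and events (newton-valued forces are
converted to BW at load).

## Problem sizes and numerical tolerances

The shipped validation uses a scaled-down cohort — 10 subjects × 40–50
cycles (~400–500 cycles) against the ~1800-cycle regime the defaults
emulate — which the estimator's spectra show is already deep in the
asymptote for a rank-5 latent structure. Key tolerances: ZMP inversion and
wrench transport are algebraic identities (1e-12); conditional inference
matches dense conditioning to 1e-9; σ² matches an independent
eigendecomposition to 1e-10; the COP anchor holds to 1e-6 m; knee moments
match the independent Newton–Euler path to 1e-8 Nm; the noiseless
end-to-end pipeline reproduces generated GRFM to better than 0.01 BW
(residual dominated by the stance-edge masking of interpolated waveforms).

## Known limitations

- The estimator is linear-Gaussian; systematic nonlinear kinematics-to-
  kinetics relationships are outside its span.
- Per-channel (not global) standardization is a choice; results depend
  mildly on it for mixed-unit feature vectors.
- The segment orientation-rate treatment and isotropic inertia are
  first-order simplifications appropriate for near-planar gait.
- Unfiltered differentiation amplifies kinematic noise in the inverse-
  dynamics stage; real deployments should low-pass filter upstream.
- The medial/lateral split is a proxy (see above), and absolute compartment
  forces from it are underestimates.
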