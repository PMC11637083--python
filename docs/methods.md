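# Methods

`footclear` estimates whole-foot minimum clearance (mFC) during the swing
phase of gait from a single foot-mounted inertial measurement unit (IMU)
plus a personalized point-cloud scan of the shoe.  This note documents the
model, the numerical choices, the synthetic-data generator that the test
suite relies on, and the limits of what passing tests demonstrate.

## The model

The shoe and the IMU rigidly attached to it are treated as one rigid body.
The world position of scan point *i* at sample *k* is

    p_i(k) = p_imu(k) + R(k) · R* · R_s2i · q_i  −  (0, 0, h_floor)

where `q_i` are the scan-frame coordinates of the point *relative to the
IMU fixture origin*, `R_s2i` rotates scan-frame vectors into IMU
coordinates (built from the fixture axes marked in the scan), `R(k)` is the
IMU orientation from dead reckoning, `R*` is a constant per-bout flat-foot
correction, and `h_floor` is a trial-level floor offset.  The instantaneous
clearance is `LP(k) = min_i p_i,z(k)`; per stride,

    mFC = min { LP(k) : k_maxHeel ≤ k ≤ k_maxToe }

with `k_maxHeel` / `k_maxToe` the argmax of heel and toe landmark height
over the stride.  This "forward swing" window deliberately avoids toe-off
and heel-strike event detection; it is undefined (and flagged invalid, not
an error) when the toe peak does not follow the heel peak, which genuinely
happens in impaired gait.  Negative mFC is reported as-is: it indicates
floor contact (scuffing), not a failure.

The rigid-body assumption holds only while the foot is unloaded, so
stance-phase "clearance" values are not meaningful and the package makes no
claims about them.

## Dead reckoning

Stance is detected by thresholding the 5-sample centered moving averages of
the accelerometer-norm deviation from standard gravity (default tolerance
0.8 m/s²) and of the gyroscope norm (default 0.3 rad/s); stance runs
shorter than 15 samples are deleted.  The thresholds are not identifiable
from first principles; they are typical strapdown-gait values, exposed in
the configuration, and pinned by closed-loop tests.  Isolated false-stance
samples do occur mid-swing when both norms briefly cross their thresholds —
the run-length filter exists precisely to delete them.

Orientation starts from the tilt implied by the mean stance specific force
(heading is set to zero and never corrected: clearance depends only on
height and relative geometry, and there is no magnetometer in scope).  Each
gyroscope sample is treated as the midpoint-rule angular rate of the
sampling interval that follows it, `R(k+1) = R(k)·expm([ω_k Δt])`.  This
convention is shared with the signal synthesizer, so on noise-free
synthetic data orientation is recovered exactly and the remaining
closed-loop error isolates the velocity/position discretisation.  During
stance the tilt is relaxed toward the gravity-measured tilt with a
complementary gain of 0.02 per sample — slow enough not to fight
integration, fast enough to bound tilt drift over long bouts.

Velocity comes from trapezoidal integration of `R(k)f(k) + g`, re-anchored
at zero on every stance run.  Two per-stride corrections address height
error: (iv) a constant world-frame acceleration bias, estimated by least
squares from the velocity ramp observed over the stride's terminal stance
run and removed as a ramp; then (v) any residual mean velocity over that
run removed as a step from the heel-strike sample onward (the impulsive
velocity error).  The order (iv) then (v) is a fixed convention; the two
corrections interact only weakly because (iv) already zeroes the mean ramp.

Position integrates the corrected velocity.  Because walking surfaces in
scope are level, zero height is re-anchored at every stance run: any
residual stance-to-stance height increment (e.g. from a sensor-frame
accelerometer bias whose world direction rotates during swing — about
2–3 mm/stride under realistic bias) is removed as a *continuous* per-stride
ramp rather than a jump, keeping the trajectory continuous.

## Flat-foot correction and floor height

Scan processing and fixture seating errors tilt the reconstructed foot by
up to a few degrees even when it stands flat.  At the first stance sample
the sole's support plane — the plane flush against the bottom of the point
cloud — is found by an iterative contact-set fit: seed with points within
3 mm of the minimum height, fit a total-least-squares plane, re-select
points within 3 mm of it along its normal, repeat to a fixed point (≤ 20
iterations), then translate the plane so no point lies below.  The minimal
rotation taking the plane normal to vertical, conjugated into the IMU frame
at that sample, gives `R*`.  On curved (rocker) soles the contact set
shifts once the cloud is rotated, so the leveling rotation is itself
iterated to a fixed point; the post-condition (residual support-plane tilt
< 0.05°) is asserted.  `R*` is constant per bout and rejected if its angle
exceeds 15°.

The floor height is the mean over strides of the median stance-phase
lowest-point height, computed from sole points only (dorsal points can
never be lowest — checked at load time, with a fall-back to all points) and
applied as a pure vertical shift to everything, IMU position included.

## Late-swing density map

For each valid stride the final third of the forward-swing window —
`[k_heel + ⌈2(k_toe − k_heel)/3⌉, k_toe]`, ceiling so the window never
reaches into the middle third — contributes the scan-frame (x, y) of the
instantaneous lowest point.  A Gaussian kernel (default σ = 10 mm) is
summed at each node of a uniform grid (default 2 mm spacing) covering the
sole bounding box padded by 3σ, and the map is normalized by its maximum,
so the peak is exactly 1 whenever any sample contributed.  Marginal
histograms along x and y count raw locations in grid-spaced bins.

## Validation statistics

The reconstructed toe-marker height is compared against a reference
trajectory (in practice optical motion capture; in tests, the generator's
analytic marker track).  The reference is linearly interpolated onto the
IMU timebase, aligned by the global lag maximizing the normalized
cross-correlation of the two height signals (pairs overlapping reference
gaps are dropped; peak correlation below 0.5 aborts), and reduced per
stride to swing key points: local maxima with topographic prominence
≥ 5 mm give MaxP1 (first), MaxP2 (last) and MinP (minimum strictly
between); a single qualifying maximum gives MaxP2 only.  Key points are
paired by matched rank, and strides where the two sources disagree on
shape class (M vs single-peak) are excluded and counted.

Differences (reconstruction − reference, mm) feed a random-intercept model
with stride nested in participant, fit by REML.  The reported limits of
agreement are `bias ± 1.96·√(σ²_participant + σ²_stride + σ²_residual)` —
the mixed-effects generalisation of Bland–Altman limits, which is the
consistent reading of an interval of that width.  Balanced designs use the
closed-form nested-ANOVA components (identical to REML at interior
solutions, clipped at zero; cross-checked against statsmodels MixedLM);
unbalanced designs go through MixedLM with a method-of-moments fallback on
singular fits.  With a single participant, or one observation per stride,
the inseparable components are folded into the residual; the total SD — the
only quantity the limits need — is unaffected.  R² is the squared Pearson
correlation of the paired heights, and is labeled as such.

## The synthetic-data generator

The generator emulates level over-ground walking: truly stationary, flat
stance phases (60% of a 1.1 s stride) alternating with swing phases built
entirely from quintic smoothsteps, hence twice continuously differentiable
— no impulsive accelerations at the stance/swing boundaries.  Defaults:
0.65 m steps, 9 cm vertical sensor excursion, 14° early-swing
plantarflexion releasing on the same schedule as the mid-swing descent,
14° late-swing dorsiflexion.  Full dorsiflexion produces an M-shaped
toe-height path; `foot_drop_factor` scales it away and leaves part of the
plantarflexion in place late in swing (the forefoot hangs low), giving the
single-peaked path of foot-drop gait.  A late-swing roll bump emulates
inversion (positive roll drops the lateral, negative-y, sole edge of a
right foot).  Scenario packs: `typical`, `foot_drop`, `inversion`
(dorsiflexion control 0.8, roll 8°), `toe_drag` (apex lowered to 2.5 cm so
the analytic clearance goes negative).

IMU signals are synthesized by central second differences of position and
interval rotation vectors, sharing the reconstruction's discretisation so
that closed-loop tests isolate algorithmic error; white Gaussian noise and
a constant sensor-frame accelerometer bias are added from a seeded
generator (seeds are mandatory; there is no hidden global randomness).
The clearance oracle evaluates the lowest-point/forward-swing/mFC
definitions directly on the exact poses over *all* cloud points, with no
integration, no flat correction and no floor estimation.

The agreement-data generator for limits-of-agreement recovery standardises
each simulated effect vector (participant, stride, residual) to exactly its
nominal SD.  With only three participants a naively sampled participant
component is χ²₂-distributed and would dominate the comparison with the
closed-form limits; controlling the realised moments makes the recovery
check a test of the estimator rather than of sampling luck
(`exact_moments=False` restores naive sampling).

What passing tests do **not** show: the generator has no shoe deformation,
no ground-contact dynamics, no sensor scale error or mounting compliance,
and its noise is white.  Real recordings violate all of these to some
degree; the agreement achievable on real data is an empirical question the
package cannot answer from simulation.

## Numerical conventions and problem sizes

All internal lengths are meters; clearances cross to millimeters only at
the output boundary.  Sample indices are 0-based with half-open windows
except the mFC window, which is inclusive of both ends by definition.
Argmax/argmin ties resolve to the earliest index.  Gravity is fixed at
9.80665 m/s².  Rotations are verified proper-orthogonal to 1e-6 per
sample (1e-9 for calibration rotations).  The default test and acceptance
workloads use bouts of 8–20 strides at 128 Hz with a ~190-point shoe cloud
— sizes chosen so every closed-loop check runs in seconds while leaving
integration drift, window jitter and estimator variance clearly visible.

## Known limitations

- Heading drift is uncorrected; horizontal positions are only relatively
  meaningful within a stride.
- The forward-swing window is undefined for gaits without a heel-then-toe
  peak ordering (e.g. complete foot drop); such strides carry no mFC.
- The floor convention assumes a level surface; slopes and steps are out
  of scope.
- Stance-phase outputs (positions during ZUPT) reflect the rigid-body
  assumption at its weakest and should not be interpreted as clearance.
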