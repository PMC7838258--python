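# Methods

## Measurement model

The belt surface is treated as rigid in the plane of its top surface, so
every marker attached to it shares the belt's instantaneous speed $v(t)$
along the (configured) direction of travel. Each reconstructed marker
position is that true position plus isotropic Gaussian noise; occlusions
and spurious reflections interrupt or pollute the unlabeled point list.
Under this model, per-frame averaging over the $N \approx 10$
simultaneously visible belt markers reduces velocity noise by
$1/\sqrt{N}$, and the spatial gate, the persistence rule and the upper
speed limit remove points that violate the rigid-belt assumption.

Assumptions that matter in practice:

* the treadmill's long axis is aligned with the lab's anteroposterior
  axis — `check_alignment` verifies this from two markers placed front
  and back at the same mediolateral position (yaw and inclination both
  reported in degrees, pass/fail against a tolerance, default 1°);
* only the speed component along the belt direction is estimated;
  lateral belt wander is ignored;
* unlabeled trajectories are consumed exactly as stored in the .c3d
  point list; no frame-to-frame re-association is attempted, which
  matches how capture software exports "unlabeled" markers across
  vendors.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `target_speed` | — | m/s | panel speed; anchors the outlier limit and all % metrics |
| gating volumes | — | m | two boxes enclosing the lateral belt edges; set per lab |
| `min_persistence` | 20 | frames | flicker rejection; inclusive (a 20-frame segment is kept) |
| `upper_limit_fraction` | 0.30 | — | samples strictly above 1.3 × target are dropped, per sample |
| `cutoff_hz` | 20 | Hz | belt-speed low-pass; high enough to keep braking-phase dips |
| `filter_order` | 4 | — | Butterworth; realized as two zero-phase passes of order 2 |
| event-marker cutoff | 6 | Hz | anatomical-trajectory low-pass before event detection |
| `max_missing_s` | 0.1 | s | longest tolerated run of frames with no belt marker |
| run/walk threshold | 2.5 | m/s | auto gait-mode split, overridable |

## Numerical choices

* **Three-frame differentiation** is the centered difference
  $(p_{i+1}-p_{i-1})f_s/2$ — the mean of the two one-frame displacement
  velocities in the window. A trailing scheme would differ only by a
  half-frame time shift. Segment endpoints yield no sample.
* **Zero-phase filtering.** "Recursive Butterworth" is applied
  forward–backward so extrema do not lag; a single-pass option exists
  (`zero_phase=False`). Each pass uses half the configured order so the
  cascade's roll-off matches it. No cut-off correction for the dual pass
  is applied by default; the classic correction is togglable
  (`cutoff_correction=True`). Zero-phase filtering is essential here:
  the timing of the stance TBV minimum is itself a reported metric.
* **Missing frames** (no surviving marker) are linearly interpolated
  before filtering and flagged; a missing run longer than
  `max_missing_s` aborts, because that means the measurement failed
  rather than flickered.
* **Edge margin.** The first/last frame of the series have no central
  difference sample and the zero-phase filter has an edge transient, so
  the series carries `edge_margin_frames = ceil(1.5 f_s / f_c)` (19
  frames at 250 Hz / 20 Hz) and `interior()` exposes the
  well-conditioned slice. Validation quantities are evaluated there.
* **Interval conventions.** Stance is `[TD, TO)` and the cycle
  `[TD, nextTD)` (half-open); profiles are resampled by linear
  interpolation onto the conventional 101-point 0–100 % grid. Sample
  (n−1) standard deviations throughout, configurable.
* **Outlier boundary.** The upper limit is strict: a sample exactly at
  1.3 × target is kept. Only an upper limit is active by default; the
  lower limit exists but is off, mirroring the method's description.

## Open design points, and what was chosen

* **Braking-reduction baseline.** The reference from which the stance
  slowdown is measured is genuinely ambiguous. Default: the filtered
  speed at the touchdown frame, which reads the drop the way belt-speed
  profiles are usually plotted. `target` and `pre_td_max` (maximum in
  the 10 % of cycle before touchdown) are selectable; the choice is
  echoed in every output.
* **Persistence counting** happens after gating and gap-splitting, i.e.
  "appears for 20 consecutive frames" is read as continuous visibility
  inside the measurement volume.
* **Walking pelvis reference** is the midpoint of the two posterior
  superior iliac spine markers.
* **Peak picking** uses a minimum inter-peak distance of 0.4 × the
  dominant stride period (from the autocorrelation of the driving
  signal) and a prominence of 10 % of its peak-to-peak range. The
  running method delimits cycles at the dominant swing-phase flexion
  maxima and takes the first/last extension peak between consecutive
  swing peaks as touchdown/toe-off, requiring the stance knee-yield
  flexion to stay below both swing peaks. Detected walking must show a
  stance fraction > 0.5 and running < 0.5; violations raise rather than
  silently misclassify (this is also what rejects time-reversed or
  wrong-mode input).

## The synthetic generator

`BeltSceneConfig` renders the canonical study conditions: 17 s captures
at 250 Hz (240 Hz selectable), a 6 m belt loop with markers every
0.24 m on both edges so exactly five per side occupy the 1.2 m top
surface, 0.2 mm marker noise (modern systems reconstruct to better than
0.1 mm; the default adds margin), 2 % per-frame occlusions, optional
static and double-speed spurious markers, and optional vendor-style
trajectory fragmentation. Belt position is the trapezoid-rule integral
of the prescribed speed, so marker displacement and ground-truth speed
agree to machine precision before noise.

The per-cycle slowdown is a raised-cosine dip parameterized by depth
(m/s), center (fraction of stance) and width (fraction of stance,
default 0.70). The width default reflects that the braking-phase dip
spans the braking phase plus its recovery — observed treadmill profiles
do not return to target until past mid-stance — and that belt/drive
inertia precludes much narrower transients; an early-centered dip may
therefore overlap touchdown, in which case the braking reduction (ground
truth and estimate alike) is measured from the touchdown-frame speed and
is smaller than the dip depth. An optional post-dip overshoot and
band-limited speed jitter are available.

Gait kinematics are simplified periodic curves built so the detectors'
defining signals peak exactly at the configured events: the
anteroposterior heel−pelvis distance peaks at touchdowns, pelvis−toe at
toe-offs, and the knee flexion angle is a baseline plus two raised-cosine
bumps per cycle (stance yield, larger swing peak) whose support edges
put extension peaks exactly at touchdown and toe-off.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: treadmill motor/controller dynamics and
step-to-step variability; soft-tissue artifact and marker-set
asymmetries (the synthetic flexion waveform is time-symmetric, unlike a
real knee); camera-dependent, anisotropic reconstruction error;
vendor-specific unlabeled-trajectory slot reuse (only a randomized
fragmentation approximation is provided); and force-plate data of any
kind.

## Problem sizes used in validation

The shipped validation (test suite and `scripts/acceptance.py`) uses
3–8 s belt scenes for recovery/robustness checks, full 17 s scenes for
event detection and cycle counts, 200 seeded scenes for the
profile-recovery grid (depths 2–25 % of target, centers 15–45 % of
stance, all eight study speeds), and 1000 random cubic trajectories for
the differentiator's closed-form check. These sizes were chosen so the
entire validation runs in well under a minute while each estimate (e.g.
a success rate over 200 scenes) remains statistically meaningful.

## Known limitations

* The C3D codec covers the marker subset of the standard (Intel byte
  order, POINT section, LABELS/LABELS2 chunking, float or signed-integer
  storage); analog channels are ignored and DEC/SGI byte orders are
  rejected with a clear error.
* Belt speed is reported along a single configured direction; a
  misconfigured axis convention shows up as a negative mean speed and
  triggers a warning, not an automatic flip.
* The event detectors are tuned for steady-state treadmill locomotion;
  accelerating protocols, crossover gaits near the walk/run threshold,
  or pathological gait may violate the stance-fraction sanity checks.
* Braking-reduction values depend on the baseline convention (above);
  comparisons across studies should state it.
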