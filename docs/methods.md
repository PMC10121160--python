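# Methods

This note records the models, parameter choices, and numerical conventions
behind `placecell`, including the places where the design was genuinely
open and what the synthetic-data tests do and do not demonstrate.

## Analysis pipeline

### Rate maps

Frames enter spatial analysis only if they are tracked and moving strictly
faster than the speed threshold (5 cm/s open field, 20 cm/s track); each
contributes 1/frame_rate seconds of occupancy and its activity sample to a
grid of half-open square bins (2 cm). Binned activity and occupancy are
smoothed with the same truncated Gaussian kernel (3σ support; σ = 3 cm open
field, σ = 5 cm track) and then divided, so the rate is a ratio of two
identically smoothed fields. In the open field, bins occupied for less than
100 ms are excluded from all subsequent analysis; the track has no
occupancy mask. Track maps are one-dimensional in arclength along each of
the eight directed paths (four arms × two running directions), with 2-cm
arclength bins; the per-cell statistic is computed on the concatenation of
the eight path maps, weighted by their smoothed occupancy.

Smoothing is mask-aware: the kernel is renormalized per output bin over the
valid-bin mask. At the wall of a circular arena an unrenormalized kernel
would average in out-of-arena zeros and attenuate edge rates; the
renormalized form leaves a uniform field exactly uniform on any mask. The
renormalization cancels algebraically in the activity/occupancy ratio, so
rates are unaffected by this choice away from masked bins — it matters
only where occupancy is smoothed alone (the p_i weights). The alternative
(no renormalization) can be recovered with `smooth_map(...,
renormalize=False)`.

### Spatial information and the shuffle test

I = Σ p_i (λ_i/λ̄) log2(λ_i/λ̄) with λ̄ = Σ p_i λ_i, bins with λ_i = 0
contributing zero, and p_i renormalized over valid bins; p_i is taken from
the smoothed occupancy so that λ̄ equals total activity over total time on
full masks. I is scale-invariant, so the unknown per-cell deconvolution
constant (and any per-cell max-normalization) cancels; this is property-
tested. A silent cell (λ̄ = 0) has undefined information and is excluded
from classification rather than scored.

Chance levels use 500 circular shuffles, each recomputing the identical
map-plus-information pipeline:

* open field — the entire position sequence is time-shifted by a uniform
  random offset between 10 s and the recording length minus 10 s, with
  wrap-around. Implementation note: a circular shift permutes frames, so
  the occupancy histogram is invariant; only the activity histogram needs
  recomputing per shuffle, which keeps 500 shuffles per cell at ~60 ms.
* track — two procedures: frame-shifting activity within each trial (arm
  traversal) independently, and frame-shifting the entire speed-thresholded
  activity sequence along the eight paths. How the two should combine is
  not obvious; this package computes both nulls, reports each percentile,
  and requires P ≥ 0.95 under **both** for the place-cell label
  (conservative intersection). Each null is also available separately.

The percentile counts nulls **strictly** below the true value, so ties
count against significance: a constant-activity cell, whose every shuffle
reproduces the same map, lands at percentile 0 rather than spuriously
passing. Classification is `percentile ≥ 0.95`.

Under the position time-shift null the false-positive rate of the 0.95
criterion on temporally independent non-spatial activity is 26/501 ≈ 0.052
(the true statistic must rank above 475 of 500 exchangeable draws), which
the calibration test verifies against the exact binomial 99% interval.

### Place fields

Seeds are 4-connected components (8-connectivity is a config switch) of at
least five bins whose rate exceeds the per-bin 95th percentile of that
cell's shuffled rate maps (per-bin rather than pooled; also switchable).
Each seed grows to the connected bins with rate ≥ 5% of the grown
component's own peak (not the global map maximum); growth stops at invalid
bins, overlapping regions merge, and the boundary is exported as a
staircase polyline along bin edges — bit-exact and reproducible, with no
subpixel smoothing. Detection is invariant to multiplying the map and
thresholds by any positive constant, and raising thresholds can only
remove fields; both are property-tested.

### Head orientation

Quaternions (w, x, y, z) from the head-mounted absolute orientation sensor
are converted through the direction-cosine matrix whose entries are the
standard quadratic polynomials (r11 = 1 − 2q_y² − 2q_z², ...), then to
roll = atan2(r23, r33), pitch = atan2(√(r11² + r12²), −r13), and
yaw = atan2(sin(roll)·r31 − cos(roll)·r21, cos(roll)·r22 − sin(roll)·r32).
Two-argument arctangents are used throughout — a single-argument arctan
cannot represent yaw beyond ±90°. Under this pitch convention a level pose
maps to pitch = 90° (pitch ∈ [0°, 180°]); the convention is preserved, not
shifted. Gimbal lock (|r33| and |r23| both < 1e-9) sets a per-sample flag
instead of raising. The mounting correction — the fixed rotation between
sensor axes and head axes — is a config parameter (identity by default,
since it depends on how the scope is mounted) and pre-multiplies each
sample's matrix. Round-trip reconstruction through `euler_to_matrix` is
exact to < 1e-9 away from gimbal lock.

### Behavior video

The LED is located per frame as the intensity-weighted centroid of the
8-connected component containing the global maximum after thresholding at
50% of that maximum; frames whose maximum clears the frame median by less
than a contrast floor are flagged and linearly interpolated across gaps of
at most 0.5 s (longer gaps stay invalid). Lens aberration is modeled as an
even-order radial polynomial (k1, k2) about a principal point, inverted by
fixed-point iteration before the affine pixel→cm map; the true aberration
model of any given camera is a calibration question, so coefficients live
in config. Speed is a central difference boxcar-smoothed over 0.25 s.

Track serialization projects positions onto the rectangle perimeter;
perimeter points within 14 cm of a corner belong to that corner's
feeder/turn zone (matching the reward-zone depth) and the rest of each arm
is interior. A traversal is a maximal interior run flanked by the arm's two
different end corners; same-end excursions are discarded. Uncompressed
8-bit grayscale AVI (fourcc GREY/Y800) is read and written by a small
RIFF-chunk module in-repo.

### Registration

Footprints are max-normalized and binarized at 0.5; centroids are
intensity-weighted means in µm. After a configured session alignment
(translation + radial scale about a center; an optional coarse grid search
±20 µm / ±2% is provided, but alignment is fundamentally a manual/QC step),
pairs within a 24-µm centroid gate are scored by Pearson correlation of the
aligned normalized footprints over their union support (union rather than
intersection so that non-overlap is penalized). Acceptance requires
distance < 6 µm AND correlation > 0.8, assigned greedily by ascending
distance, one-to-one. A probabilistic mixture model over the
distance/correlation distributions is deliberately out of scope; the
deterministic thresholds are the operative rule. The sub-FOV procedure
draws 500 circle centers uniformly such that the 1-mm circle stays inside
the field of view and counts centroids per circle (mean, SD with ddof=1).

## Synthetic data: what it emulates

The generator supplies sessions with exactly the statistical structure the
analysis assumes, so green tests certify the pipeline's logic, not its
behavior on real data (no photon noise, no motion artifacts, no
deconvolution errors, no overdispersed bursting, no behavioral
stereotypy).

* **Open-field walker** — waypoint-seeking bounded walk: heading relaxes
  toward a goal (gain 4 /s) with angular noise 0.6 rad/√s; speed is an
  Ornstein-Uhlenbeck process around 22 cm/s (τ = 1 s, clipped 3–45 cm/s);
  goals renew on capture or every 20 s, emulating pellets thrown at random
  locations every 20 s. Goal radii are drawn as R·u^0.35, oversampling the
  wall region the way open-field rats do. With defaults, a 14-min 15-Hz
  run occupies 92–96% of in-arena 2-cm bins for ≥ 100 ms (measured over
  seeds 0–4), meeting the generator's ≥ 90% coverage contract. No claim is
  made that these defaults match real rat gait statistics — the tasks'
  speed distributions are not published.
* **Track runner** — feeder-to-feeder journeys alternating ends, direct
  2.5-m arm with probability 0.7 versus the 5-m three-arm detour, run speed
  ~45 ± 8 cm/s (so the 20-cm/s threshold keeps traversals), 1.5-s feeder
  dwells at near-zero speed, ≤ ±1 cm lateral jitter within the 10-cm path.
  Ground-truth traversal labels are emitted for round-trip testing.
* **Activity** — expectation law E[a_t] = (baseline + (peak −
  baseline)·exp(−‖x_t − c‖²/2σ²)) / frame_rate; sampled as Poisson counts
  at that mean times unit-mean gamma(shape 3) amplitudes, giving the
  sparse, continuous, nonnegative traces deconvolution produces. Defaults:
  σ = 10 cm, peak 5 a.u./s, baseline 1 a.u./s (5:1); untuned cells emit
  baseline-rate activity everywhere so classifiers cannot key on overall
  rate. Absolute scale is arbitrary by design. Directional track cells
  apply their tuning only on listed path ids and baseline elsewhere.
* **Orientation** — quaternion streams integrated from OU angular velocity
  (defaults 30/30/90 °/s SD, τ = 0.5 s); unit norm is maintained to 1e-9.
* **LED video** — Gaussian spot (amplitude 180, σ = 2 px) on a noisy
  background (level 12, SD 2); frames with the spot mapped outside the
  image or contrast under 5 noise SDs are flagged rather than silently
  clipped.

## Known limitations

* Field-peak localization is sampling-noise-limited. With 2-cm bins,
  σ = 3 cm smoothing, and a 14-min session, each smoothed bin estimate
  pools only a few seconds of occupancy, so for a σ = 10 cm field (whose
  rate falls just 8% within 4 cm of its center) the argmax bin wanders
  several centimeters at realistic deconvolved event rates: roughly half
  of detected field peaks land within 4 cm of the true center at the
  default 5 a.u./s peak rate, rising only to ~80% at eight times that
  rate. Noiseless activity recovers every center to within one bin, so
  this is estimator variance, not bias. Users needing precise field
  centers should prefer the rate-weighted field centroid or longer
  sessions over the peak bin.
* Trial-wise track shuffles preserve per-trial activity totals, so cells
  whose activity differs across trials for non-spatial reasons (drift,
  state) are partially protected — but power against weak directional
  tuning is limited when a path has few traversals.
* The classifier's 0.95 criterion is calibrated for temporally independent
  activity; strong slow autocorrelation in real deconvolved traces is
  exactly what the circular shuffle is designed to respect, but the
  synthetic calibration cannot certify that property on real data.
* Registration assumes footprint shape is stable across sessions up to
  translation/radial scale; nonrigid tissue deformation and chains of
  more than two sessions are out of scope.
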