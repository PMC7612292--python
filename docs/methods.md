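# Methods

## Model

A magnetically shielded room's interior, away from sources, carries a static
magnetic field that is both divergence- and curl-free.  Such a field is the
gradient of a scalar potential satisfying Laplace's equation, so it admits an
expansion in the gradients of regular solid harmonics:

    B(r) = Σ_{l=1}^{l_max} Σ_{m=-l}^{l} β_lm ∇( r^l S_lm(θ, φ) ).

`S_lm` are the real spherical harmonics, orthonormal on the unit sphere,
built from Condon–Shortley-free associated Legendre functions with
`cos(mφ)` for m > 0 and `sin(|m|φ)` for m < 0.  The l = 0 term has zero
gradient and is excluded.  Degree 1 contributes the three uniform fields
(∝ x̂, ŷ, ẑ); degree l contributes 2l + 1 fields scaling as length^(l−1).
Any physical constant in front of the expansion is absorbed into the fitted
coefficients, whose units are therefore nT·m^−(l−1).

Because `r^l S_lm` is a homogeneous Cartesian polynomial, each basis field is
evaluated as an exact symbolic gradient (built once per index with sympy and
cached as a vectorised function).  This is exact at the coordinate origin and
on the polar axis, where spherical-coordinate differentiation is singular.
A finite-difference evaluator exists only in the tests, as an independent
oracle.

### Measurement model

Channel m, at room-frame position r_m(t) with unit sensitive axis ρ_m(t),
records

    B_m(t) = e_m + Σ_lm β_lm ∇(r^l S_lm)(r_m(t)) · ρ_m(t) + ε,    ε ~ N(0, σ²)

with unit gain assumed (gain error is ~1 %/nT and is not modeled) and e_m a
static per-channel offset (on-sensor nulling field, cell heater, light
shift).  Stacking channels channel-major (all samples of channel 1, then
channel 2, …) gives Y = Xβ with a design matrix whose first M columns are
the per-channel indicator block and whose remaining l_max(l_max + 2) columns
are the basis fields projected on each row's axis.  The fit is the
rank-revealing pseudoinverse solution (`numpy.linalg.lstsq`, singular values
below max(dim)·ε·σ_max treated as zero); on rank deficiency — e.g. zero
motion, where the offset block and the uniform-field columns are collinear —
the minimum-norm solution is returned and a `DegenerateFitWarning` raised.
Condition numbers are recorded per fit and warned about above 1e8.  No
regularization is applied.

### Sliding-window correction

The room field drifts slowly (passing traffic, wall vibration), so the model
is refit on windows of the data; the step defaults to half the window.
Where 50 %-overlapping windows both cover a sample, their predictions are
averaged — this avoids step discontinuities at window boundaries; a
"latest-window" mode is available for real-time emulation.  A trailing
partial window is merged into the last full window rather than fitted alone
(tiny fits are ill-conditioned).  The assembled prediction is low-pass
filtered at 2 Hz (5th-order zero-phase Butterworth) before subtraction:
genuine head movement lives below ~2 Hz, and the camera jitter that leaks
into the prediction above that band would otherwise be injected into the
corrected data.  By default the full prediction including the offsets is
subtracted (the corrected data is then zero-mean); a flag retains the
offsets.

## Pose reconstruction

Rigid-body poses come from K ≥ 3 retroreflective markers with known
rigid-frame coordinates.  Per frame, the optimal rigid transform is the SVD
(Kabsch) solution with the reflection branch corrected so det(R) = +1;
collinear templates are rejected.  Occlusion gaps are filled in two passes:
frames missing exactly one marker are completed from the rigid constraint
given the other markers; remaining interior gaps are filled by cubic splines
per marker and coordinate (no extrapolation at the series boundary).  Field
data are decimated to the analysis rate with a polyphase anti-aliasing
filter; pose translations are linearly interpolated and rotations slerped
onto the same grid.  Slerp coincides with linear interpolation for the small
inter-frame rotations of head motion but stays on the rotation manifold.
The trigger-latency offset between the two acquisition systems is an
explicit parameter (`sync_offset`), not inferred.

Coordinate frames: the library is frame-agnostic; everything is expressed in
whatever right-handed room frame the pose data uses.  The synthetic module
uses z-up with the origin at the room centre.

## Filtering

All offline filters are Butterworth applied forward–backward
(`sosfiltfilt`): zero phase, so measured data and model predictions stay
aligned for the subtraction; the effective magnitude response is the squared
one-pass response and the effective order doubles.  Named profiles:
`triaxial` (60 Hz low-pass order 4; band-stops at 50 Hz and 120 Hz order 5,
default width ±2 Hz — the widths are configurable since mains/camera
interference bandwidth varies by site), `opmeg-positions` (2 Hz low-pass
order 6) and `opmeg-predictions` (2 Hz low-pass order 5).

## Evaluation statistics

* **R²** — 1 − SS_res/SS_tot with SS_tot about the *grand* mean pooled over
  all channels and times.  Per-channel means would discard the offset
  variance the model explains.
* **k-fold CV** — rows of the stacked (channel, time) system are assigned to
  folds uniformly at random with a fixed seed (contiguous temporal blocks
  available as an option).  Random folds interleave times, so a field that
  drifts slowly still scores well; that is exactly why the temporal 80/20
  hold-out is computed alongside — a hold-out score that departs from the
  training score while CV does not is the signature of temporal
  nonstationarity rather than spatial model failure.
* **Cross-run transfer** — harmonic coefficients frozen, offsets refit on
  the target run by default (they are per-run device state from on-sensor
  nulling, not room field); a flag freezes them too.
* **Shielding factor** — 20·log10(ASD_measured/ASD_residual) per channel and
  frequency, ASD from Welch with Hann taper, 50 % overlap, segments of
  ~10 s (capped at the record length) and *no detrending*, so the DC bin is
  meaningful; summarised as channel mean ± SEM.  Zero residual power clamps
  to +300 dB with a warning.
* **RMS reduction** — 100·(1 − RMS(corrected)/RMS(measured)) per channel on
  raw values; the offset columns deliberately absorb DC, so offset removal
  counts toward the reduction.  A `detrend` flag removes channel means
  first.

## Synthetic scenarios

The simulator generates exactly what the model assumes, plus the
imperfections that matter:

* **Array** — 43 sensors on a Fibonacci spiral over the upper 110° of a
  10 cm sphere, each with a radial and an exactly orthogonal tangential
  channel (86 channels).  Deterministic.
* **Room field** — order-2 by default: uniform components of 0.4–0.8 nT and
  gradients of order 1 nT/m, consistent with a degaussed OPM-dedicated room;
  per-channel offsets drawn uniformly from ±(0.1–2) nT; dynamic-range guard
  at ±5.56 nT.  Optional drift modulates the l ≤ 2 coefficients with a
  unit-RMS sum of random tones below 0.02 Hz, scaled by `drift_amplitude`
  (external interference is spatially smooth, hence low-degree only).
* **Motion** — translations and small-angle Euler rotations are Gaussian
  processes low-passed to 2 Hz (order-8 zero-phase Butterworth) and rescaled
  so the per-axis peak-to-peak excursion equals the requested range
  (defaults: 0.6 m, 0.5 rad), emulating large natural head movements.
* **Markers** — four markers with ~16 cm in-plane and ~9 cm out-of-plane
  spread (near-coplanar rigs leave one rotation axis weakly constrained and
  amplify camera jitter), isotropic jitter of 0.1 mm (an assumed camera
  noise floor), and Poisson occlusions (0.02 /s per marker, mean 0.3 s).
* **Noise** — per-sample Gaussian σ = 0.02 nT per channel, an aggregate of
  intrinsic sensor noise and unmodeled broadband pickup.

All randomness flows through one `numpy` generator per call; a scenario is
fully determined by its seed.

What the simulator does *not* contain — and what passing tests therefore do
not demonstrate about real recordings: cable-motion artefacts, gain
nonlinearity (~1 %/nT), cross-talk between on-sensor coils, brain signal,
non-harmonic near-field sources, and camera noise that is correlated across
markers.  Synthetic recovery being exact shows the estimator is correct
under its own assumptions, not that a real room is order-2.

## Problem sizes and numerical choices

The test-bench and the acceptance script use desk-scale versions of the
reference conditions: the exact-recovery check runs the full 86-channel
array for 30 s at 240 Hz; the cross-validation and window-length studies run
at a 30 Hz analysis rate (movement content is below 2 Hz, so this is
generous sampling) with 30–240 s durations.  The stacked systems then range
from 2·10⁵ to 6·10⁵ rows with up to 94 columns, which a dense SVD solves in
seconds.

Tolerances and tie-breaks worth knowing: orientations must be unit-norm to
1e−6 on input; rotation matrices orthogonal to 1e−9; dual-axis pairs
orthogonal to 1e−3 rad when declared; window boundaries are computed in
samples (`round(window·fs)`); filter pad lengths are clamped for very short
series; JSON serialisation writes floats at full precision, so model files
and tables round-trip bit-exactly.

## Known limitations

Offsets are refit in every window — a slow (e.g. Bayesian) update would be
more faithful to their physical time constant.  The 2 Hz prediction filter
hard-codes the movement/jitter crossover; a site with faster movements needs
a different cutoff.  Real-time operation, per-sensor nulling-coil command
generation and interior/exterior field separation are out of scope.
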