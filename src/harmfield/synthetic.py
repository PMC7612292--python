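"""Synthetic shielded-room scenarios with known ground truth.

Everything the pipeline consumes can be generated here: a dual-axis head
array, smooth rigid-body motion through the room, the background field of a
magnetically shielded room expressed in the same harmonic basis the model
fits (so recovery can be checked exactly), and optical marker trajectories
with camera jitter and occlusion gaps.

Default magnitudes mirror a well-degaussed OPM-dedicated room: a residual
uniform field under ~1 nT with spatial gradients of order 1 nT/m (1000 pT/m),
per-channel offsets of 0.1–2 nT from on-sensor nulling, head translations of
about 0.6 m with spectral content below 2 Hz, and a ±5.56 nT sensor dynamic
range.  Slow temporal drift, when enabled, modulates only the low-degree
(l ≤ 2) coefficients: external interference seen from the room's centre is
spatially smooth.

All randomness flows through one seeded generator per call; identical seeds
give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.spatial.transform import Rotation

from .field_model import FieldRecording
from .harmonics import harmonic_indices, n_harmonic_coefficients, solid_harmonic_gradient
from .rigid_motion import MarkerTrajectory, RigidPoseSeries, SensorArray, channel_world_pose

__all__ = [
    "RoomFieldSpec",
    "NoiseSpec",
    "default_room",
    "default_marker_template",
    "make_head_array",
    "simulate_trajectory",
    "simulate_recording",
    "simulate_markers",
    "simulate_dataset",
]


@dataclass
class RoomFieldSpec:
    """Ground-truth harmonic description of the room's background field.

    ``beta`` follows the flattened (l, m) ordering in nT·m^−(l−1).
    ``drift_amplitude`` (same units) sets the RMS of a slow random modulation
    added to each coefficient; modulation is band-limited to
    ``drift_bandwidth`` Hz and restricted to degrees ``l ≤ drift_max_degree``.
    """

    l_max: int
    beta: np.ndarray
    drift_amplitude: float = 0.0
    drift_bandwidth: float = 0.02  # Hz; external interference is slow
    drift_max_degree: int = 2
    extent: float = 1.0  # m, half-width of the volume of validity

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.beta) != n_harmonic_coefficients(self.l_max):
            raise ValueError("beta length must be l_max (l_max + 2)")
        if self.drift_amplitude < 0 or not 0 < self.drift_bandwidth <= 0.1:
            raise ValueError("drift amplitude must be >= 0 and bandwidth in (0, 0.1] Hz")

    def field_at(self, positions: np.ndarray, beta: np.ndarray | None = None) -> np.ndarray:
        """Vector field (…, 3) in nT at the given positions (m)."""
        beta = self.beta if beta is None else np.asarray(beta, dtype=float)
        out = np.zeros(np.asarray(positions, dtype=float).shape)
        for j, idx in enumerate(harmonic_indices(self.l_max)):
            out += beta[j] * solid_harmonic_gradient(idx, positions)
        return out


@dataclass
class NoiseSpec:
    """Stochastic imperfections of the recording chain.

    ``sensor_sigma`` is the per-sample Gaussian noise of one channel in nT —
    an aggregate of intrinsic sensor noise and unmodelled broadband pickup.
    ``offset_range`` bounds the magnitude of per-channel static offsets
    (random sign).  ``marker_jitter`` is the isotropic per-frame standard
    deviation of the motion-capture positions; occlusions arrive per marker
    as a Poisson process of ``occlusion_rate`` events/s lasting an
    exponential time of mean ``occlusion_duration`` s.
    """

    sensor_sigma: float = 0.02  # nT per sample
    offset_range: tuple[float, float] = (0.1, 2.0)  # nT
    marker_jitter: float = 1e-4  # m (0.1 mm camera noise floor, an assumption)
    occlusion_rate: float = 0.02  # events / s / marker
    occlusion_duration: float = 0.3  # s, mean

    def __post_init__(self) -> None:
        if min(self.sensor_sigma, self.marker_jitter, self.occlusion_rate, self.occlusion_duration) < 0:
            raise ValueError("all noise parameters must be non-negative")


def default_room(drift_amplitude: float = 0.0) -> RoomFieldSpec:
    """Order-2 room: sub-nT uniform field plus ~1 nT/m gradients."""
    beta = np.array(
        [
            1.2, -0.8, 1.6,  # l=1: uniform field, components ~0.4-0.8 nT
            0.9, -0.6, 0.7, 0.5, -0.8,  # l=2: gradients ~1 nT/m
        ]
    )
    return RoomFieldSpec(l_max=2, beta=beta, drift_amplitude=drift_amplitude)


def default_marker_template() -> np.ndarray:
    """Four retroreflective markers on the scanner-cast (rigid frame, m).

    Markers are spread in all three directions (~16 cm in-plane, ~9 cm
    out-of-plane) so every rotation axis is well constrained; near-coplanar
    rigs leave one axis poorly determined and amplify camera jitter.
    """
    return np.array(
        [
            [0.09, 0.00, 0.10],
            [-0.09, 0.02, 0.11],
            [0.00, 0.10, 0.19],
            [0.00, -0.08, 0.10],
        ]
    )


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def make_head_array(n_sensors: int = 43, dual_axis: bool = True, head_radius: float = 0.10) -> SensorArray:
    """Quasi-uniform sensor layout on a spherical cap (a scanner-cast).

    Sensors sit on a Fibonacci spiral over the upper ~110° of a sphere of
    ``head_radius``; each contributes a radially oriented channel and, when
    ``dual_axis``, a second tangential channel exactly orthogonal to it.
    Construction is deterministic.
    """
    if n_sensors < 1:
        raise ValueError("need at least one sensor")
    cap = np.cos(np.deg2rad(110.0))
    k = np.arange(n_sensors)
    cos_theta = 1.0 - (1.0 - cap) * (k + 0.5) / n_sensors
    theta = np.arccos(cos_theta)
    phi = k * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    radial = np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    ids, positions, orientations, pairs = [], [], [], []
    for s in range(n_sensors):
        r = radial[s]
        pos = head_radius * r
        ids.append(f"S{s:02d}_rad")
        positions.append(pos)
        orientations.append(r)
        if dual_axis:
            ref = np.array([0.0, 0.0, 1.0]) if abs(r[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
            tan = np.cross(ref, r)
            tan /= np.linalg.norm(tan)
            ids.append(f"S{s:02d}_tan")
            positions.append(pos)
            orientations.append(tan)
            pairs.append((2 * s, 2 * s + 1))
    return SensorArray(ids, np.array(positions), np.array(orientations), pairs)


# ---------------------------------------------------------------------------
# Motion
# ---------------------------------------------------------------------------

def _smooth_noise(rng: np.random.Generator, n: int, fs: float, bandwidth: float, columns: int) -> np.ndarray:
    """Unit-variance Gaussian noise low-passed to ``bandwidth`` Hz, (n, columns)."""
    white = rng.standard_normal((n, columns))
    if bandwidth >= fs / 2:
        return white
    sos = butter(8, bandwidth, btype="low", fs=fs, output="sos")
    padlen = min(n - 1, 3 * 2 * sos.shape[0] * 3)  # clamp for very short series
    smooth = sosfiltfilt(sos, white, axis=0, padlen=padlen)
    std = smooth.std(axis=0)
    std[std == 0] = 1.0
    return smooth / std


def simulate_trajectory(
    duration: float,
    fs: float,
    translation_range: float = 0.6,
    rotation_range: float = 0.5,
    bandwidth: float = 2.0,
    seed: int = 0,
) -> RigidPoseSeries:
    """Smooth pseudo-random rigid motion about the room centre.

    Translations and (small-angle) Euler rotations are independent Gaussian
    processes low-passed to ``bandwidth`` Hz (head movement is slow) and
    rescaled so the peak-to-peak excursion per axis equals
    ``translation_range`` m / ``rotation_range`` rad.  Rotations are composed
    into proper rotation matrices.  Deterministic given ``seed``.
    """
    if not 0 < bandwidth <= 2.0:
        raise ValueError("movement bandwidth must be in (0, 2] Hz")
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration too short for the sample rate")
    rng = np.random.default_rng(seed)
    ts = np.arange(n) / fs

    def scaled(target: float) -> np.ndarray:
        if target <= 0:
            return np.zeros((n, 3))
        x = _smooth_noise(rng, n, fs, bandwidth, 3)
        p2p = x.max(axis=0) - x.min(axis=0)
        p2p[p2p == 0] = 1.0
        return x * (target / p2p)

    translations = scaled(translation_range)
    angles = scaled(rotation_range)
    rotations = Rotation.from_euler("xyz", angles).as_matrix()
    return RigidPoseSeries(ts, rotations, translations)


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

def _drift_modulation(rng: np.random.Generator, ts: np.ndarray, bandwidth: float) -> np.ndarray:
    """Unit-RMS slow modulation: a sum of random tones below ``bandwidth`` Hz."""
    n_tones = 8
    freqs = rng.uniform(bandwidth / 10.0, bandwidth, n_tones)
    phases = rng.uniform(0, 2 * np.pi, n_tones)
    amps = rng.uniform(0.5, 1.0, n_tones)
    sig = np.zeros_like(ts)
    for f, p, a in zip(freqs, phases, amps):
        sig += a * np.sin(2 * np.pi * f * ts + p)
    return sig / np.sqrt(np.mean(sig**2))


def simulate_recording(
    array: SensorArray,
    poses: RigidPoseSeries,
    room: RoomFieldSpec,
    noise: NoiseSpec,
    seed: int = 0,
) -> tuple[FieldRecording, dict]:
    """Forward-model a recording: project the room field onto each moving channel.

    ``B_m(t) = Σ β_lm(t) ∇(r^l S_lm)(r_m(t)) · ρ_m(t) + offset_m + ε`` with
    unit gain.  Returns the recording and a ground-truth dict with the
    (possibly time-varying) coefficients, offsets and noise draw.
    """
    rng = np.random.default_rng(seed)
    ts = poses.timestamps
    fs = 1.0 / float(np.median(np.diff(ts))) if len(ts) > 1 else 1.0
    positions, orientations = channel_world_pose(array, poses)
    M, T, _ = positions.shape

    # basis projections per coefficient: (n_coef, M, T)
    proj = np.empty((n_harmonic_coefficients(room.l_max), M, T))
    flat_p = positions.reshape(-1, 3)
    flat_o = orientations.reshape(-1, 3)
    for j, idx in enumerate(harmonic_indices(room.l_max)):
        proj[j] = np.einsum("ij,ij->i", solid_harmonic_gradient(idx, flat_p), flat_o).reshape(M, T)

    beta_t = np.repeat(room.beta[:, None], T, axis=1)
    if room.drift_amplitude > 0:
        for j, idx in enumerate(harmonic_indices(room.l_max)):
            if idx.l <= room.drift_max_degree:
                beta_t[j] += room.drift_amplitude * _drift_modulation(rng, ts, room.drift_bandwidth)

    data = np.einsum("jmt,jt->mt", proj, beta_t)
    lo, hi = noise.offset_range
    offsets = rng.uniform(lo, hi, M) * rng.choice([-1.0, 1.0], M)
    data += offsets[:, None]
    if noise.sensor_sigma > 0:
        data += rng.normal(0.0, noise.sensor_sigma, data.shape)
    recording = FieldRecording(list(array.channel_ids), data, fs, t_start=float(ts[0]))
    truth = {"beta": beta_t, "beta_static": room.beta.copy(), "offsets": offsets, "noise_sigma": noise.sensor_sigma}
    return recording, truth


def simulate_markers(
    poses: RigidPoseSeries,
    template: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> MarkerTrajectory:
    """Optical marker trajectories for a pose series, with jitter and gaps.

    Markers follow ``R_t · template_k + t_t`` plus isotropic Gaussian jitter;
    occlusion intervals (Poisson arrivals, exponential durations) are blanked
    to NaN.  Ground-truth poses are the input; deterministic given ``seed``.
    """
    template = default_marker_template() if template is None else np.asarray(template, dtype=float)
    noise = NoiseSpec() if noise is None else noise
    rng = np.random.default_rng(seed)
    ts = poses.timestamps
    K, T = template.shape[0], len(ts)
    positions = np.einsum("tij,kj->kti", poses.rotations, template) + poses.translations[None, :, :]
    if noise.marker_jitter > 0:
        positions = positions + rng.normal(0.0, noise.marker_jitter, positions.shape)
    if noise.occlusion_rate > 0 and T > 1:
        t_end = ts[-1]
        for k in range(K):
            t = ts[0] + rng.exponential(1.0 / noise.occlusion_rate)
            while t < t_end:
                dur = rng.exponential(noise.occlusion_duration)
                gap = (ts >= t) & (ts < t + dur)
                # never blank the endpoints: spline filling needs interior gaps
                gap[0] = gap[-1] = False
                positions[k, gap] = np.nan
                t += dur + rng.exponential(1.0 / noise.occlusion_rate)
    return MarkerTrajectory(ts, positions, template)


def simulate_dataset(
    duration: float = 300.0,
    fs: float = 240.0,
    n_sensors: int = 43,
    seed: int = 0,
    room: RoomFieldSpec | None = None,
    noise: NoiseSpec | None = None,
    translation_range: float = 0.6,
    rotation_range: float = 0.5,
) -> dict:
    """One-call scenario builder used by the CLI and the test-bench.

    Defaults reproduce the reference conditions: an 86-channel dual-axis
    array, 240 Hz analysis rate, 5 minutes of ~0.6 m movements through an
    order-2 room field with 0.1–2 nT channel offsets.  Returns a dict with
    ``array``, ``poses``, ``recording``, ``markers``, ``room``, ``noise``
    and ``truth``.
    """
    room = default_room() if room is None else room
    noise = NoiseSpec() if noise is None else noise
    rng = np.random.default_rng(seed)
    s_traj, s_rec, s_mark = (int(r) for r in rng.integers(0, 2**31 - 1, 3))
    array = make_head_array(n_sensors=n_sensors)
    poses = simulate_trajectory(
        duration, fs, translation_range=translation_range, rotation_range=rotation_range, seed=s_traj
    )
    recording, truth = simulate_recording(array, poses, room, noise, seed=s_rec)
    markers = simulate_markers(poses, noise=noise, seed=s_mark)
    return {
        "array": array,
        "poses": poses,
        "recording": recording,
        "markers": markers,
        "room": room,
        "noise": noise,
        "truth": truth,
    }
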