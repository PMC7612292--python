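"""Rigid-body pose reconstruction from optical marker data.

A rigid plate of retroreflective markers is fixed to the sensor holder; a
motion-capture system reports each marker's room-frame position over time,
with gaps wherever a marker is occluded.  This module recovers the rigid
transform (rotation + translation) at every frame, fills occlusion gaps, and
maps the per-channel sensor geometry into the room frame, where the field
model is expressed.

Gap filling is two-stage, in the order used for whole-head recordings:
first *pattern-based* (a frame missing exactly one marker is completed from
the rigid constraint given the other three or more), then cubic-spline
interpolation of any remaining interior gaps.

All rotations are proper (det = +1); pose interpolation for resampling uses
spherical linear interpolation on quaternions, which coincides with linear
interpolation for the small inter-frame rotations of head movement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation, Slerp

__all__ = [
    "MarkerTrajectory",
    "RigidPoseSeries",
    "SensorArray",
    "kabsch",
    "fill_gaps_pattern",
    "fill_gaps_spline",
    "solve_poses",
    "synchronize_and_resample",
    "channel_world_pose",
]


def _check_increasing(timestamps: np.ndarray) -> np.ndarray:
    timestamps = np.asarray(timestamps, dtype=float)
    if timestamps.ndim != 1 or (len(timestamps) > 1 and np.any(np.diff(timestamps) <= 0)):
        raise ValueError("timestamps must be a strictly increasing 1-D array")
    return timestamps


@dataclass
class MarkerTrajectory:
    """Room-frame marker positions over time plus the rigid-frame template.

    ``positions`` is ``(K, T, 3)`` in metres with NaN rows marking occluded
    samples; ``template`` is ``(K, 3)``, the marker coordinates in the rigid
    (holder) frame.  At least 3 markers are needed to solve a pose.
    """

    timestamps: np.ndarray
    positions: np.ndarray
    template: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = _check_increasing(self.timestamps)
        self.positions = np.asarray(self.positions, dtype=float)
        self.template = np.asarray(self.template, dtype=float)
        K = self.template.shape[0]
        if self.template.shape != (K, 3) or K < 3:
            raise ValueError("template must be (K, 3) with K >= 3")
        if self.positions.shape != (K, len(self.timestamps), 3):
            raise ValueError("positions must be (K, T, 3) matching template and timestamps")

    @property
    def n_markers(self) -> int:
        return self.template.shape[0]

    def visible(self) -> np.ndarray:
        """Boolean (K, T): marker fully observed at that frame."""
        return ~np.any(np.isnan(self.positions), axis=2)

    def copy(self) -> "MarkerTrajectory":
        return MarkerTrajectory(self.timestamps.copy(), self.positions.copy(), self.template.copy())


@dataclass
class RigidPoseSeries:
    """Time-stamped rigid transform of the holder: room = R · rigid + t."""

    timestamps: np.ndarray
    rotations: np.ndarray  # (T, 3, 3) proper rotation matrices
    translations: np.ndarray  # (T, 3) metres

    def __post_init__(self) -> None:
        self.timestamps = _check_increasing(self.timestamps)
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        T = len(self.timestamps)
        if self.rotations.shape != (T, 3, 3) or self.translations.shape != (T, 3):
            raise ValueError("rotations must be (T, 3, 3) and translations (T, 3)")
        rtr = np.einsum("tij,tik->tjk", self.rotations, self.rotations)
        if np.max(np.abs(rtr - np.eye(3))) > 1e-9:
            raise ValueError("rotations must be orthogonal to 1e-9")
        if np.any(np.linalg.det(self.rotations) < 0):
            raise ValueError("rotations must be proper (det = +1)")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class SensorArray:
    """Per-channel geometry in the rigid frame.

    Dual-axis sensors contribute two channels with (near-)orthogonal
    sensitive axes; ``axis_pairs`` lists such channel-index pairs so the
    orthogonality declaration can be validated.
    """

    channel_ids: list[str]
    positions: np.ndarray  # (M, 3) m, rigid frame
    orientations: np.ndarray  # (M, 3) unit vectors, rigid frame
    axis_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        M = len(self.channel_ids)
        if self.positions.shape != (M, 3) or self.orientations.shape != (M, 3):
            raise ValueError("positions and orientations must be (M, 3)")
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("orientations must be unit-norm")
        for i, j in self.axis_pairs:
            cosang = abs(float(self.orientations[i] @ self.orientations[j]))
            if cosang > np.sin(1e-3):  # within 1e-3 rad of orthogonal
                raise ValueError(f"declared dual-axis pair ({i}, {j}) is not orthogonal")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def to_json(self, path) -> None:
        payload = {
            "channels": [
                {"id": cid, "position": self.positions[i].tolist(), "orientation": self.orientations[i].tolist()}
                for i, cid in enumerate(self.channel_ids)
            ],
            "axis_pairs": [list(p) for p in self.axis_pairs],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SensorArray":
        with open(path) as fh:
            payload = json.load(fh)
        chans = payload["channels"]
        return cls(
            channel_ids=[c["id"] for c in chans],
            positions=np.array([c["position"] for c in chans], dtype=float),
            orientations=np.array([c["orientation"] for c in chans], dtype=float),
            axis_pairs=[tuple(p) for p in payload.get("axis_pairs", [])],
        )


# ---------------------------------------------------------------------------
# Pose solving
# ---------------------------------------------------------------------------

def kabsch(template: np.ndarray, observed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform: minimise ``Σ‖R·template_k + t − observed_k‖²``.

    SVD solution with the reflection branch corrected (the singular direction
    with the smallest singular value is flipped when needed) so that
    ``det(R) = +1`` always.

    Returns ``(R, t)`` with ``R`` a (3, 3) proper rotation and ``t`` a 3-vector.
    """
    template = np.asarray(template, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if template.shape != observed.shape or template.ndim != 2 or template.shape[0] < 3:
        raise ValueError("template and observed must be matching (K, 3) with K >= 3")
    ct = template.mean(axis=0)
    co = observed.mean(axis=0)
    A = template - ct
    # Collinear templates leave a free rotation about the line: reject.
    if np.linalg.matrix_rank(A, tol=1e-10 * max(1.0, np.abs(A).max())) < 2:
        raise np.linalg.LinAlgError("template markers are collinear; pose is not solvable")
    H = A.T @ (observed - co)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = co - R @ ct
    return R, t


def fill_gaps_pattern(markers: MarkerTrajectory) -> MarkerTrajectory:
    """Complete frames missing exactly one marker from the rigid constraint.

    For such a frame the pose is solved from the visible markers and the
    occluded marker is placed at ``R · template + t``.  Frames missing two or
    more markers are passed through untouched (for spline filling).
    """
    out = markers.copy()
    vis = markers.visible()
    n_missing = (~vis).sum(axis=0)
    targets = np.flatnonzero((n_missing == 1) & (vis.sum(axis=0) >= 3))
    for f in targets:
        present = vis[:, f]
        R, t = kabsch(markers.template[present], markers.positions[present, f])
        missing = int(np.flatnonzero(~present)[0])
        out.positions[missing, f] = R @ markers.template[missing] + t
    return out


def fill_gaps_spline(markers: MarkerTrajectory) -> MarkerTrajectory:
    """Fill remaining interior gaps with cubic splines, per marker per axis.

    A gap touching the start or end of the series cannot be bridged (no
    extrapolation) and raises ``ValueError``.
    """
    out = markers.copy()
    ts = markers.timestamps
    vis = markers.visible()
    for k in range(markers.n_markers):
        obs = vis[k]
        if obs.all():
            continue
        if not obs[0] or not obs[-1]:
            raise ValueError(f"marker {k}: gap at sequence boundary; spline filling needs interior gaps")
        spline = CubicSpline(ts[obs], markers.positions[k, obs], axis=0)
        out.positions[k, ~obs] = spline(ts[~obs])
    return out


def solve_poses(markers: MarkerTrajectory) -> RigidPoseSeries:
    """Per-frame Kabsch fit of the template onto gap-free observed markers."""
    if not markers.visible().all():
        raise ValueError("marker data still contains gaps; fill gaps before solving poses")
    T = len(markers.timestamps)
    rotations = np.empty((T, 3, 3))
    translations = np.empty((T, 3))
    for f in range(T):
        rotations[f], translations[f] = kabsch(markers.template, markers.positions[:, f])
    return RigidPoseSeries(markers.timestamps, rotations, translations)


# ---------------------------------------------------------------------------
# Alignment and resampling
# ---------------------------------------------------------------------------

def _resample_poses(poses: RigidPoseSeries, new_ts: np.ndarray) -> RigidPoseSeries:
    translations = np.column_stack(
        [np.interp(new_ts, poses.timestamps, poses.translations[:, i]) for i in range(3)]
    )
    slerp = Slerp(poses.timestamps, Rotation.from_matrix(poses.rotations))
    rotations = slerp(new_ts).as_matrix()
    return RigidPoseSeries(new_ts, rotations, translations)


def synchronize_and_resample(field, poses: RigidPoseSeries, target_fs: float, sync_offset: float = 0.0):
    """Bring a field recording and a pose series onto one time grid.

    ``sync_offset`` (s) is added to the pose timestamps to account for the
    shared trigger pulse latency.  The field is decimated with an
    anti-aliasing low-pass when ``target_fs`` is below its rate (upsampling of
    field data is not supported); pose translations are linearly interpolated
    and rotations slerped onto the same grid.

    Returns ``(field_at_target_fs, poses_at_target_fs)``.
    """
    from scipy.signal import resample_poly
    from .field_model import FieldRecording

    pose_ts = poses.timestamps + sync_offset
    field_ts = field.times
    t0 = max(field_ts[0], pose_ts[0])
    t1 = min(field_ts[-1], pose_ts[-1])
    if t1 <= t0:
        raise ValueError("field and pose series do not overlap in time after applying sync_offset")

    if np.isclose(field.fs, target_fs):
        data = field.data
        ts = field_ts
    elif field.fs > target_fs:
        from fractions import Fraction

        frac = Fraction(target_fs / field.fs).limit_denominator(10000)
        data = resample_poly(field.data, frac.numerator, frac.denominator, axis=1)
        ts = field_ts[0] + np.arange(data.shape[1]) / target_fs
    else:
        raise ValueError("target_fs above the field sample rate; record faster or lower target_fs")

    keep = (ts >= t0) & (ts <= t1)
    new_ts = ts[keep]
    out_field = FieldRecording(field.channel_ids, data[:, keep], target_fs, t_start=new_ts[0])
    shifted = RigidPoseSeries(pose_ts, poses.rotations, poses.translations)
    out_poses = _resample_poses(shifted, new_ts)
    return out_field, out_poses


def channel_world_pose(array: SensorArray, poses: RigidPoseSeries) -> tuple[np.ndarray, np.ndarray]:
    """Map channel geometry through the pose series into the room frame.

    Returns ``(positions, orientations)`` with shape ``(M, T, 3)``:
    ``position[m, t] = R_t p_m + t_t`` and ``orientation[m, t] = R_t ρ_m``.
    """
    positions = np.einsum("tij,mj->mti", poses.rotations, array.positions) + poses.translations[None, :, :]
    orientations = np.einsum("tij,mj->mti", poses.rotations, array.orientations)
    return positions, orientations
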