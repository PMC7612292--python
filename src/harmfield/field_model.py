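"""Offset-plus-harmonics regression of the background field, and its removal.

The measured value of channel *m* at time *t* is modelled as

    B_m(t) = e_offset,m + Σ_lm β_lm [ ∇(r^l S_lm)(r_m(t)) · ρ_m(t) ] + ε

where ``r_m(t)`` and ``ρ_m(t)`` are the channel's room-frame position and
sensitive axis (from the rigid-body pose), ``e_offset,m`` a static per-channel
bias (on-sensor nulling field, cell heater, light shift), and ε Gaussian
noise.  Stacking all channels and times channel-major gives a single linear
system ``Y = X β`` solved by pseudoinverse; the fitted model predicts the
movement artefact at any pose, seen or unseen, and subtracting the prediction
from the data removes it.

Because the room field drifts slowly, the model is refit on sliding windows
(step = half the window by default) and the per-window predictions are
averaged where windows overlap, avoiding step discontinuities at window
boundaries.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .harmonics import basis_block, n_harmonic_coefficients
from .preprocess import butter_lowpass
from .rigid_motion import RigidPoseSeries, SensorArray, channel_world_pose

__all__ = [
    "FieldRecording",
    "HarmonicModel",
    "WindowedModelSeries",
    "DegenerateFitWarning",
    "DynamicRangeWarning",
    "build_design_matrix",
    "stack_response",
    "fit",
    "predict",
    "sliding_correct",
]

logger = logging.getLogger(__name__)

#: Magnetometer dynamic range (nT); values beyond it saturate the sensor and
#: also incur gain errors of order 1 %/nT, so they are flagged.
DEFAULT_DYNAMIC_RANGE_NT = 5.56

#: Condition numbers above this trigger a degeneracy warning on fit.
CONDITION_WARNING_THRESHOLD = 1e8


class DegenerateFitWarning(UserWarning):
    """The design matrix was rank-deficient or severely ill-conditioned."""


class DynamicRangeWarning(UserWarning):
    """Field values exceed the configured magnetometer dynamic range."""


@dataclass
class FieldRecording:
    """Channels × time magnetometer data in nT at a fixed sample rate."""

    channel_ids: list[str]
    data: np.ndarray  # (M, N) nT
    fs: float  # Hz
    t_start: float = 0.0
    dynamic_range: float = DEFAULT_DYNAMIC_RANGE_NT

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_ids):
            raise ValueError("data must be (M, N) with M = len(channel_ids)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("field data must be finite")
        if self.fs <= 0:
            raise ValueError("sample rate must be positive")
        if self.data.size and np.max(np.abs(self.data)) > self.dynamic_range:
            warnings.warn(
                f"field values exceed the ±{self.dynamic_range} nT dynamic range",
                DynamicRangeWarning,
                stacklevel=2,
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_samples) / self.fs

    def copy_with(self, data: np.ndarray) -> "FieldRecording":
        return FieldRecording(list(self.channel_ids), data, self.fs, self.t_start, self.dynamic_range)


@dataclass
class HarmonicModel:
    """A fitted offset-plus-harmonics model.

    ``beta`` follows the flattened (l, m) ordering, with units
    nT·m^−(l−1); ``offsets`` maps channel id → nT.
    """

    l_max: int
    beta: np.ndarray
    offsets: dict[str, float]
    condition_number: float = np.nan
    residual_variance: float = np.nan
    rank: int | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.beta) != n_harmonic_coefficients(self.l_max):
            raise ValueError("beta length must be l_max (l_max + 2)")

    def to_dict(self) -> dict:
        return {
            "l_max": self.l_max,
            "beta": self.beta.tolist(),
            "offsets": {k: float(v) for k, v in self.offsets.items()},
            "condition_number": float(self.condition_number),
            "residual_variance": float(self.residual_variance),
            "rank": self.rank,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HarmonicModel":
        return cls(
            l_max=int(d["l_max"]),
            beta=np.array(d["beta"], dtype=float),
            offsets=dict(d["offsets"]),
            condition_number=float(d.get("condition_number", np.nan)),
            residual_variance=float(d.get("residual_variance", np.nan)),
            rank=d.get("rank"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "HarmonicModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class WindowedModelSeries:
    """Sequence of per-window models with their time supports."""

    window: float  # s
    step: float  # s
    models: list[tuple[float, float, HarmonicModel]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.step > self.window:
            raise ValueError("step must not exceed the window length")
        starts = [m[0] for m in self.models]
        if starts != sorted(starts):
            raise ValueError("windows must be ordered by start time")

    def to_dict(self) -> dict:
        return {
            "window": self.window,
            "step": self.step,
            "models": [
                {"t_start": t0, "t_end": t1, "model": m.to_dict()} for t0, t1, m in self.models
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WindowedModelSeries":
        return cls(
            window=float(d["window"]),
            step=float(d["step"]),
            models=[
                (float(e["t_start"]), float(e["t_end"]), HarmonicModel.from_dict(e["model"]))
                for e in d["models"]
            ],
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "WindowedModelSeries":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Design matrix and fitting
# ---------------------------------------------------------------------------

def stack_response(data: np.ndarray) -> np.ndarray:
    """Stack (M, T) data channel-major: all times of channel 1, then 2, …"""
    return np.asarray(data, dtype=float).reshape(-1)


def build_design_matrix(positions: np.ndarray, orientations: np.ndarray, l_max: int) -> np.ndarray:
    """Assemble the regression design matrix for M channels over T samples.

    Parameters
    ----------
    positions, orientations
        ``(M, T, 3)`` room-frame channel positions (m) and unit axes.
    l_max
        Harmonic expansion degree.

    Returns
    -------
    ``(M·T, M + l_max (l_max + 2))`` matrix.  Rows are channel-major to match
    :func:`stack_response`.  The first ``M`` columns are the offset indicator
    block Γ (column m is 1 exactly on channel-m rows); the remaining columns
    are the harmonic basis projected on each row's axis.
    """
    positions = np.asarray(positions, dtype=float)
    orientations = np.asarray(orientations, dtype=float)
    if positions.shape != orientations.shape or positions.ndim != 3 or positions.shape[2] != 3:
        raise ValueError("positions and orientations must both be (M, T, 3)")
    M, T, _ = positions.shape
    n_harm = n_harmonic_coefficients(l_max)
    X = np.zeros((M * T, M + n_harm))
    for m in range(M):
        X[m * T : (m + 1) * T, m] = 1.0
    X[:, M:] = basis_block(positions.reshape(-1, 3), orientations.reshape(-1, 3), l_max)
    return X


def _infer_l_max(n_harm: int) -> int:
    l = int(round(np.sqrt(n_harm + 1) - 1))
    if l * (l + 2) != n_harm:
        raise ValueError(f"{n_harm} harmonic columns do not correspond to any integer l_max")
    return l


def fit(Y: np.ndarray, X: np.ndarray, channel_ids: list[str]) -> HarmonicModel:
    """Solve ``β = X† Y`` by rank-revealing pseudoinverse.

    ``Y`` is the channel-major stacked response and ``X`` the matrix from
    :func:`build_design_matrix`; the first ``len(channel_ids)`` columns are
    the per-channel offsets.  On rank deficiency (e.g. zero motion, where the
    offset block and the uniform-field columns are collinear) the minimum-norm
    solution is returned and a :class:`DegenerateFitWarning` is raised.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or Y.ndim != 1 or X.shape[0] != Y.shape[0]:
        raise ValueError("X must be 2-D with rows(X) == len(Y)")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in regression inputs")
    M = len(channel_ids)
    l_max = _infer_l_max(X.shape[1] - M)

    rcond = max(X.shape) * np.finfo(float).eps
    coef, _, rank, svals = np.linalg.lstsq(X, Y, rcond=rcond)
    cond = float(svals[0] / svals[-1]) if svals[-1] > 0 else np.inf
    if rank < X.shape[1] or cond > CONDITION_WARNING_THRESHOLD:
        warnings.warn(
            f"design matrix is degenerate (rank {rank}/{X.shape[1]}, cond {cond:.3g}); "
            "minimum-norm solution returned",
            DegenerateFitWarning,
            stacklevel=2,
        )
    resid = Y - X @ coef
    dof = max(X.shape[0] - rank, 1)
    model = HarmonicModel(
        l_max=l_max,
        beta=coef[M:],
        offsets={cid: float(coef[i]) for i, cid in enumerate(channel_ids)},
        condition_number=cond,
        residual_variance=float(resid @ resid / dof),
        rank=int(rank),
    )
    logger.debug("fit: l_max=%d rank=%d cond=%.3g", l_max, rank, cond)
    return model


def predict(
    model: HarmonicModel,
    positions: np.ndarray,
    orientations: np.ndarray,
    channel_ids: list[str],
    include_offsets: bool = True,
) -> np.ndarray:
    """Evaluate the model at arbitrary channel poses.

    ``positions``/``orientations`` are ``(M, T, 3)``; returns an ``(M, T)``
    array in nT.  Poses need not have been seen during fitting — this is what
    lets the model predict the artefact of novel movements.
    """
    missing = [c for c in channel_ids if c not in model.offsets]
    if missing:
        raise KeyError(f"channels not in model offset table: {missing}")
    M, T, _ = positions.shape
    harm = basis_block(positions.reshape(-1, 3), orientations.reshape(-1, 3), model.l_max)
    pred = (harm @ model.beta).reshape(M, T)
    if include_offsets:
        pred = pred + np.array([model.offsets[c] for c in channel_ids])[:, None]
    return pred


# ---------------------------------------------------------------------------
# Sliding-window correction
# ---------------------------------------------------------------------------

def _window_slices(n_samples: int, win_n: int, step_n: int) -> list[tuple[int, int]]:
    """Window sample ranges; a trailing partial window is merged into the last
    full window rather than fitted alone (tiny fits are ill-conditioned)."""
    if win_n > n_samples:
        raise ValueError("window longer than the recording")
    slices = []
    start = 0
    while start + win_n <= n_samples:
        slices.append((start, start + win_n))
        start += step_n
    if not slices:
        slices = [(0, n_samples)]
    last_start, last_end = slices[-1]
    if last_end < n_samples:
        slices[-1] = (last_start, n_samples)
    return slices


def sliding_correct(
    recording: FieldRecording,
    poses: RigidPoseSeries,
    array: SensorArray,
    l_max: int,
    window: float,
    step: float | None = None,
    prediction_filter: bool = True,
    prediction_cutoff: float = 2.0,
    prediction_filter_order: int = 5,
    subtract_offsets: bool = True,
    overlap: str = "average",
) -> tuple[FieldRecording, WindowedModelSeries]:
    """Fit per-window harmonic models and subtract the predicted artefact.

    Parameters
    ----------
    window, step
        Window length and model update interval in seconds; ``step`` defaults
        to half the window.  Short windows track temporal field drift better;
        long windows average down motion-tracking noise.
    prediction_filter
        Low-pass the assembled prediction (zero-phase Butterworth,
        ``prediction_cutoff`` Hz, ``prediction_filter_order``) before
        subtraction, since genuine movement lies below ~2 Hz and camera
        jitter above it would otherwise be injected into the corrected data.
    subtract_offsets
        Subtract the full model prediction including per-channel offsets
        (default); if False only the harmonic part is removed and channel DC
        is retained.
    overlap
        ``"average"`` blends predictions from all windows covering a sample;
        ``"latest"`` uses the most recent window only (real-time emulation).

    Returns
    -------
    ``(corrected, models)`` — the corrected recording and the per-window
    model series.
    """
    if overlap not in ("average", "latest"):
        raise ValueError("overlap must be 'average' or 'latest'")
    step = window / 2 if step is None else step
    if step <= 0 or step > window:
        raise ValueError("step must be in (0, window]")
    if len(poses) != recording.n_samples or not np.allclose(poses.timestamps, recording.times, atol=0.5 / recording.fs):
        raise ValueError("poses must be aligned to the recording's sample grid")

    positions, orientations = channel_world_pose(array, poses)
    M, N = recording.n_channels, recording.n_samples
    win_n = int(round(window * recording.fs))
    step_n = max(int(round(step * recording.fs)), 1)
    slices = _window_slices(N, win_n, step_n)

    pred_sum = np.zeros((M, N))
    counts = np.zeros(N)
    models = []
    for i0, i1 in slices:
        X = build_design_matrix(positions[:, i0:i1], orientations[:, i0:i1], l_max)
        Y = stack_response(recording.data[:, i0:i1])
        model = fit(Y, X, recording.channel_ids)
        coef = np.concatenate([[model.offsets[c] for c in recording.channel_ids], model.beta])
        pred = (X @ coef).reshape(M, i1 - i0)
        if not subtract_offsets:
            pred = pred - np.array([model.offsets[c] for c in recording.channel_ids])[:, None]
        if overlap == "average":
            pred_sum[:, i0:i1] += pred
            counts[i0:i1] += 1
        else:
            pred_sum[:, i0:i1] = pred
            counts[i0:i1] = 1
        t = recording.times
        models.append((float(t[i0]), float(t[i1 - 1] + 1.0 / recording.fs), model))
    logger.info("sliding_correct: %d windows of %.3g s (step %.3g s)", len(slices), window, step)

    prediction = pred_sum / counts
    if prediction_filter and prediction_cutoff < recording.fs / 2:
        prediction = butter_lowpass(prediction, recording.fs, prediction_cutoff, prediction_filter_order)
    corrected = recording.data - prediction
    out = FieldRecording(
        list(recording.channel_ids), corrected, recording.fs, recording.t_start, recording.dynamic_range
    )
    return out, WindowedModelSeries(window=window, step=step, models=models)
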