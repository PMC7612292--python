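"""Evaluation statistics for the field model and its corrections.

Three families of statistics:

* **Variance explained** — the coefficient of determination
  ``R² = 1 − Σ(y − ŷ)² / Σ(y − ⟨y⟩)²`` with the mean taken over *all*
  channels and times pooled (a single grand mean, not per-channel means),
  evaluated in-sample, under 10-fold cross-validation, on an 80/20 temporal
  hold-out, and across independent runs.  A temporal hold-out that departs
  from the training score while random-fold CV does not is the signature of a
  field drifting in time rather than a model failing in space.

* **Shielding factor** — ``20 log10( A_measured(f) / A_residual(f) )`` per
  channel and frequency, with A the Welch amplitude spectral density;
  summarised across channels as mean ± standard error.

* **RMS reduction** — the percentage decrease in per-channel RMS after
  correction, computed on the raw (not mean-removed) values by default since
  the model's offset columns deliberately absorb channel DC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.signal import welch

from .field_model import (
    FieldRecording,
    HarmonicModel,
    build_design_matrix,
    fit,
    predict,
    stack_response,
)
from .rigid_motion import RigidPoseSeries, SensorArray, channel_world_pose

__all__ = [
    "EvaluationReport",
    "r_squared",
    "kfold_cv",
    "holdout_80_20",
    "cross_run_transfer",
    "shielding_factor_spectrum",
    "rms_reduction",
]

#: Cap applied to shielding factors where residual power underflows to zero.
SHIELDING_CLAMP_DB = 300.0


@dataclass
class EvaluationReport:
    """Container for the statistics produced by a pipeline run."""

    r2_pooled: float | None = None
    cv_in_sample: tuple[float, float] | None = None  # (mean, sd)
    cv_out_of_sample: tuple[float, float] | None = None
    holdout_train_r2: float | None = None
    holdout_test_r2: float | None = None
    shielding_freqs: np.ndarray | None = None
    shielding_db: np.ndarray | None = None  # (M, F)
    shielding_mean: np.ndarray | None = None
    shielding_sem: np.ndarray | None = None
    rms_reduction_pct: np.ndarray | None = None  # (M,)
    extras: dict = dataclass_field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, tuple):
                return list(v)
            return v

        return {k: conv(v) for k, v in self.__dict__.items()}


def r_squared(measured: np.ndarray, modelled: np.ndarray) -> float:
    """Pooled coefficient of determination over all channels and times.

    The total sum of squares is taken about the grand mean of the stacked
    measured values.  Raises if the measured data has zero total variance
    (R² is then undefined).
    """
    measured = np.asarray(measured, dtype=float).reshape(-1)
    modelled = np.asarray(modelled, dtype=float).reshape(-1)
    if measured.shape != modelled.shape:
        raise ValueError("measured and modelled must have equal lengths")
    ss_tot = float(np.sum((measured - measured.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: measured data has zero total variance")
    ss_res = float(np.sum((measured - modelled) ** 2))
    return 1.0 - ss_res / ss_tot


def _stacked_system(recording: FieldRecording, poses: RigidPoseSeries, array: SensorArray, l_max: int):
    positions, orientations = channel_world_pose(array, poses)
    X = build_design_matrix(positions, orientations, l_max)
    Y = stack_response(recording.data)
    return X, Y


def kfold_cv(
    recording: FieldRecording,
    poses: RigidPoseSeries,
    array: SensorArray,
    l_max: int,
    k: int = 10,
    seed: int = 0,
    folds: str = "random",
) -> dict:
    """k-fold cross-validated R² of the harmonic model.

    Rows of the stacked (channel, time) system are assigned to folds either
    uniformly at random (``folds="random"``, seeded and deterministic) or as
    contiguous temporal blocks (``folds="blocks"``, for temporal-leakage
    sensitive use).  Each fold is held out once; R² is computed in-sample on
    the training rows and out-of-sample on the held-out rows.

    Returns a dict with per-fold arrays and (mean, sd) summaries.
    """
    if folds not in ("random", "blocks"):
        raise ValueError("folds must be 'random' or 'blocks'")
    X, Y = _stacked_system(recording, poses, array, l_max)
    n = len(Y)
    if folds == "random":
        rng = np.random.default_rng(seed)
        assignment = rng.permutation(n) % k
    else:
        M, N = recording.data.shape
        block = (np.arange(N) * k) // N  # contiguous time blocks, same for every channel
        assignment = np.tile(block, M)
    r2_in, r2_out, degenerate = [], [], []
    for fold in range(k):
        test = assignment == fold
        train = ~test
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = fit(Y[train], X[train], recording.channel_ids)
        degenerate.append(any(issubclass(w.category, UserWarning) for w in caught))
        coef = np.concatenate([[model.offsets[c] for c in recording.channel_ids], model.beta])
        r2_in.append(r_squared(Y[train], X[train] @ coef))
        r2_out.append(r_squared(Y[test], X[test] @ coef))
    r2_in = np.array(r2_in)
    r2_out = np.array(r2_out)
    return {
        "r2_in_sample": r2_in,
        "r2_out_of_sample": r2_out,
        "in_sample": (float(r2_in.mean()), float(r2_in.std(ddof=1))),
        "out_of_sample": (float(r2_out.mean()), float(r2_out.std(ddof=1))),
        "degenerate_folds": degenerate,
    }


def holdout_80_20(
    recording: FieldRecording,
    poses: RigidPoseSeries,
    array: SensorArray,
    l_max: int,
    train_fraction: float = 0.8,
) -> tuple[float, float]:
    """Train on the first ``train_fraction`` of samples, test on the rest.

    A purely temporal split: all channels of the early samples train the
    model, all channels of the late samples evaluate it.  Returns
    ``(train_r2, test_r2)``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    N = recording.n_samples
    n_train = int(round(train_fraction * N))
    if n_train == 0 or n_train == N:
        raise ValueError("split leaves an empty train or test segment")
    positions, orientations = channel_world_pose(array, poses)
    X_tr = build_design_matrix(positions[:, :n_train], orientations[:, :n_train], l_max)
    Y_tr = stack_response(recording.data[:, :n_train])
    model = fit(Y_tr, X_tr, recording.channel_ids)
    coef = np.concatenate([[model.offsets[c] for c in recording.channel_ids], model.beta])
    X_te = build_design_matrix(positions[:, n_train:], orientations[:, n_train:], l_max)
    Y_te = stack_response(recording.data[:, n_train:])
    return r_squared(Y_tr, X_tr @ coef), r_squared(Y_te, X_te @ coef)


def cross_run_transfer(
    model: HarmonicModel,
    recording: FieldRecording,
    poses: RigidPoseSeries,
    array: SensorArray,
    refit_offsets: bool = True,
) -> float:
    """Apply a frozen harmonic model to an independent run and report R².

    The harmonic coefficients stay frozen.  By default the per-channel
    offsets are refit on the target run (they reflect per-run on-sensor
    nulling state, not the room field); pass ``refit_offsets=False`` to keep
    the stored offsets.
    """
    if set(recording.channel_ids) - set(model.offsets):
        raise KeyError("frozen model does not cover all channels of the target recording")
    positions, orientations = channel_world_pose(array, poses)
    harm = predict(model, positions, orientations, recording.channel_ids, include_offsets=False)
    if refit_offsets:
        offsets = (recording.data - harm).mean(axis=1)
    else:
        offsets = np.array([model.offsets[c] for c in recording.channel_ids])
    pred = harm + offsets[:, None]
    return r_squared(recording.data, pred)


def shielding_factor_spectrum(
    measured: FieldRecording,
    corrected: FieldRecording,
    nperseg: int | None = None,
) -> dict:
    """Frequency-resolved shielding factor of a correction, per channel.

    ``20 log10( ASD_measured / ASD_residual )`` with amplitude spectral
    densities from Welch's method (Hann taper, 50 % overlap, no detrending so
    the DC bin is meaningful).  Frequencies where the residual power
    underflows to zero are clamped at +300 dB and flagged.

    Returns ``{"freqs", "shielding_db" (M, F), "mean", "sem", "clamped"}``.
    """
    if measured.data.shape != corrected.data.shape or not np.isclose(measured.fs, corrected.fs):
        raise ValueError("measured and corrected recordings must share shape and sample rate")
    N = measured.n_samples
    if nperseg is None:
        nperseg = min(N, int(round(10.0 * measured.fs)))  # ~10 s segments
    f, p_meas = welch(measured.data, fs=measured.fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, detrend=False, axis=-1)
    _, p_res = welch(corrected.data, fs=corrected.fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, detrend=False, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sf = 20.0 * np.log10(np.sqrt(p_meas) / np.sqrt(p_res))
    clamped = ~np.isfinite(sf)
    if np.any(clamped):
        warnings.warn("zero residual power at some frequencies; shielding factor clamped", UserWarning, stacklevel=2)
        sf = np.where(clamped, SHIELDING_CLAMP_DB, sf)
    mean = sf.mean(axis=0)
    sem = sf.std(axis=0, ddof=1) / np.sqrt(sf.shape[0]) if sf.shape[0] > 1 else np.zeros_like(mean)
    return {"freqs": f, "shielding_db": sf, "mean": mean, "sem": sem, "clamped": clamped}


def rms_reduction(measured: FieldRecording, corrected: FieldRecording, detrend: bool = False) -> dict:
    """Percentage decrease in per-channel RMS after correction.

    ``100 (1 − RMS(corrected) / RMS(measured))`` per channel, on raw values
    by default (the model's offset columns absorb DC, so offset removal
    legitimately counts towards the reduction); ``detrend=True`` removes each
    channel's mean first.

    Returns ``{"per_channel" (%), "mean", "sem"}``.
    """
    if measured.data.shape != corrected.data.shape:
        raise ValueError("recordings must share shape")
    dm = measured.data - measured.data.mean(axis=1, keepdims=True) if detrend else measured.data
    dc = corrected.data - corrected.data.mean(axis=1, keepdims=True) if detrend else corrected.data
    rms_m = np.sqrt(np.mean(dm**2, axis=1))
    rms_c = np.sqrt(np.mean(dc**2, axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (1.0 - rms_c / rms_m)
    sem = float(pct.std(ddof=1) / np.sqrt(len(pct))) if len(pct) > 1 else 0.0
    return {"per_channel": pct, "mean": float(pct.mean()), "sem": sem}
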