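"""Temporal filtering for field, position and prediction streams.

Three named profiles cover the pipeline's needs:

``triaxial``
    Field-mapping recordings: 4th-order 60 Hz low-pass plus 5th-order
    band-stops at 50 Hz (mains) and 120 Hz (motion-camera infrared pickup).
``opmeg-positions``
    Position data ahead of model fitting: 6th-order 2 Hz low-pass — camera
    jitter above 2 Hz otherwise leaks into the fitted field model.
``opmeg-predictions``
    Model predictions ahead of subtraction: 5th-order 2 Hz low-pass,
    since genuine head movement lives below ~2 Hz.

All filters are applied forward–backward (zero phase), so the effective
magnitude response is the squared Butterworth response and the stated order
doubles; phase alignment between measured data and model predictions is what
makes the artefact subtraction clean.  Band-stop widths default to ±2 Hz
about the nominal line and are configurable.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = ["butter_lowpass", "butter_bandstop", "standard_chain", "PROFILES"]


def _apply_sos(sos: np.ndarray, signal: np.ndarray) -> np.ndarray:
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] == 0:
        return signal.copy()
    return sosfiltfilt(sos, signal, axis=-1)


def butter_lowpass(signal: np.ndarray, fs: float, cutoff: float, order: int) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last (time) axis.

    DC gain is exactly 1, so per-channel offsets pass through unchanged.
    """
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2) = (0, {fs / 2}), got {cutoff}")
    sos = butter(order, cutoff, btype="low", fs=fs, output="sos")
    return _apply_sos(sos, signal)


def butter_bandstop(signal: np.ndarray, fs: float, band: tuple[float, float], order: int) -> np.ndarray:
    """Zero-phase Butterworth band-stop over ``band = (low, high)`` Hz."""
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band must satisfy 0 < low < high < fs/2, got {band} at fs={fs}")
    sos = butter(order, (lo, hi), btype="bandstop", fs=fs, output="sos")
    return _apply_sos(sos, signal)


#: Named filter chains: list of (kind, kwargs) applied in order.
PROFILES: dict[str, list[tuple[str, dict]]] = {
    "triaxial": [
        ("lowpass", {"cutoff": 60.0, "order": 4}),
        ("bandstop", {"band": (48.0, 52.0), "order": 5}),
        ("bandstop", {"band": (118.0, 122.0), "order": 5}),
    ],
    "opmeg-positions": [("lowpass", {"cutoff": 2.0, "order": 6})],
    "opmeg-predictions": [("lowpass", {"cutoff": 2.0, "order": 5})],
}


def standard_chain(signal: np.ndarray, fs: float, profile: str, overrides: dict | None = None) -> np.ndarray:
    """Apply a named filter profile to a channels × time array.

    ``overrides`` may replace any stage keyword, keyed by ``"<kind><i>.<key>"``
    style is overkill here — instead pass a full replacement stage list under
    ``overrides={"stages": [...]}`` when the defaults do not fit.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown filter profile {profile!r}; known: {sorted(PROFILES)}")
    stages = (overrides or {}).get("stages", PROFILES[profile])
    out = np.asarray(signal, dtype=float)
    for kind, kwargs in stages:
        if kind == "lowpass":
            out = butter_lowpass(out, fs, **kwargs)
        elif kind == "bandstop":
            out = butter_bandstop(out, fs, **kwargs)
        else:
            raise ValueError(f"unknown filter stage kind {kind!r}")
    return out
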