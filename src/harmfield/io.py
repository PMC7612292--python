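"""File formats, run configuration and the end-to-end pipeline.

All on-disk formats are plain text: delimited numeric tables (first column
time in seconds, header row naming the remaining columns) for field, pose
and marker data; JSON for sensor geometry, fitted models and evaluation
reports; YAML or JSON for run configuration.  Floats are written with 17
significant digits so tables round-trip bit-exactly.

Instrument-native formats are deliberately not parsed here; adapters should
convert to these tables (``write_field_table`` / ``write_pose_table`` are the
hook points).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .field_model import FieldRecording, sliding_correct
from .metrics import r_squared, rms_reduction, shielding_factor_spectrum
from .preprocess import butter_lowpass
from .rigid_motion import (
    MarkerTrajectory,
    RigidPoseSeries,
    SensorArray,
    fill_gaps_pattern,
    fill_gaps_spline,
    solve_poses,
    synchronize_and_resample,
)

__all__ = [
    "TableFormatError",
    "ConfigError",
    "RunConfig",
    "read_field_table",
    "write_field_table",
    "read_pose_table",
    "write_pose_table",
    "read_marker_table",
    "write_marker_table",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


class TableFormatError(ValueError):
    """A delimited table violated the expected layout; carries a line number."""


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def _parse_table(path, allow_nan: bool = False) -> tuple[list[str], np.ndarray]:
    """Parse a delimited numeric table, reporting errors with line numbers."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""] if lines and lines[-1].strip() == "" else lines
    if not lines:
        raise TableFormatError(f"{path}: empty file")
    delim = "," if "," in lines[0] else "\t"
    header_cells = [c.strip() for c in lines[0].split(delim)]

    def _is_number(cell: str) -> bool:
        try:
            float(cell)
            return True
        except ValueError:
            return False

    if all(_is_number(c) for c in header_cells if c != ""):
        raise TableFormatError(f"{path}, line 1: missing header row (all cells numeric)")
    ncol = len(header_cells)
    data = np.empty((len(lines) - 1, ncol))
    for i, ln in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in ln.split(delim)]
        if len(cells) != ncol:
            raise TableFormatError(f"{path}, line {i}: expected {ncol} columns, found {len(cells)}")
        for j, cell in enumerate(cells):
            if cell == "" or cell.lower() == "nan":
                if not allow_nan:
                    raise TableFormatError(f"{path}, line {i}: missing value in column {j + 1}")
                data[i - 2, j] = np.nan
            else:
                try:
                    data[i - 2, j] = float(cell)
                except ValueError:
                    raise TableFormatError(f"{path}, line {i}: non-numeric cell {cell!r} in column {j + 1}") from None
    return header_cells, data


def _write_table(path, header: list[str], data: np.ndarray) -> None:
    np.savetxt(path, data, fmt=_FLOAT_FMT, delimiter=",", header=",".join(header), comments="")


def read_field_table(path) -> FieldRecording:
    """Read a field table: columns ``time`` then one per channel (nT)."""
    header, data = _parse_table(path)
    if len(header) < 2:
        raise TableFormatError(f"{path}: need a time column and at least one channel")
    if data.shape[0] < 2:
        raise TableFormatError(f"{path}: need at least two samples to infer the sample rate")
    times = data[:, 0]
    dt = np.diff(times)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        raise TableFormatError(f"{path}: time column must increase uniformly")
    fs = 1.0 / float(dt[0])
    return FieldRecording(header[1:], data[:, 1:].T, fs, t_start=float(times[0]))


def write_field_table(recording: FieldRecording, path) -> None:
    _write_table(
        path,
        ["time"] + list(recording.channel_ids),
        np.column_stack([recording.times, recording.data.T]),
    )


def read_pose_table(path) -> RigidPoseSeries:
    """Read a pose table: columns time, qw, qx, qy, qz, tx, ty, tz."""
    from scipy.spatial.transform import Rotation

    header, data = _parse_table(path)
    expected = ["time", "qw", "qx", "qy", "qz", "tx", "ty", "tz"]
    if [h.lower() for h in header] != expected:
        raise TableFormatError(f"{path}, line 1: header must be {','.join(expected)}")
    quats = data[:, [2, 3, 4, 1]]  # scipy order (x, y, z, w)
    rotations = Rotation.from_quat(quats).as_matrix()
    return RigidPoseSeries(data[:, 0], rotations, data[:, 5:8])


def write_pose_table(poses: RigidPoseSeries, path) -> None:
    from scipy.spatial.transform import Rotation

    q = Rotation.from_matrix(poses.rotations).as_quat()  # (x, y, z, w)
    data = np.column_stack([poses.timestamps, q[:, 3], q[:, 0], q[:, 1], q[:, 2], poses.translations])
    _write_table(path, ["time", "qw", "qx", "qy", "qz", "tx", "ty", "tz"], data)


def read_marker_table(path, template: np.ndarray) -> MarkerTrajectory:
    """Read a marker table: time then x/y/z triplets per marker; blank/NaN = gap."""
    header, data = _parse_table(path, allow_nan=True)
    K = np.asarray(template).shape[0]
    if len(header) != 1 + 3 * K:
        raise TableFormatError(f"{path}: expected 1 + 3*{K} columns for {K} markers, found {len(header)}")
    positions = data[:, 1:].reshape(-1, K, 3).transpose(1, 0, 2)
    return MarkerTrajectory(data[:, 0], positions, template)


def write_marker_table(markers: MarkerTrajectory, path) -> None:
    K = markers.n_markers
    header = ["time"] + [f"m{k}_{ax}" for k in range(K) for ax in "xyz"]
    flat = markers.positions.transpose(1, 0, 2).reshape(len(markers.timestamps), 3 * K)
    _write_table(path, header, np.column_stack([markers.timestamps, flat]))


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one correction run needs, serialisable for provenance.

    Motion may come either as a precomputed pose table (``poses``) or as raw
    marker data (``markers`` + ``marker_template``), in which case gaps are
    pattern-filled, spline-filled and the poses solved per frame.
    """

    field: str
    geometry: str
    output_dir: str
    poses: str | None = None
    markers: str | None = None
    marker_template: str | None = None
    l_max: int = 2
    window: float = 10.0
    step: float | None = None
    prediction_filter: bool = True
    position_filter: bool = True
    position_filter_cutoff: float = 2.0
    position_filter_order: int = 6
    target_fs: float | None = None
    sync_offset: float = 0.0
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            payload = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
        try:
            return cls(**payload)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from None

    def validate(self) -> None:
        for name in ("field", "geometry", "poses", "markers", "marker_template"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"config path {name} = {p!r} does not exist")
        if self.poses is None and self.markers is None:
            raise ConfigError("config must provide either poses or markers")
        if self.markers is not None and self.marker_template is None:
            raise ConfigError("marker data requires marker_template")
        if not 1 <= self.l_max <= 6:
            raise ConfigError("l_max must be in 1..6")
        if self.window <= 0:
            raise ConfigError("window must be positive")

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _load_poses(config: RunConfig) -> RigidPoseSeries:
    if config.poses is not None:
        return read_pose_table(config.poses)
    with open(config.marker_template) as fh:
        template = np.array(json.load(fh), dtype=float)
    markers = read_marker_table(config.markers, template)
    markers = fill_gaps_pattern(markers)
    markers = fill_gaps_spline(markers)
    return solve_poses(markers)


def run_pipeline(config: RunConfig) -> dict:
    """Load → align → filter → sliding-correct → evaluate → write outputs.

    Writes ``corrected.csv``, ``models.json`` and ``report.json`` (with a
    provenance block) into ``config.output_dir`` and returns the report dict.
    Deterministic given the config.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    array = SensorArray.from_json(config.geometry)
    recording = read_field_table(config.field)
    poses = _load_poses(config)
    if config.target_fs is not None or config.sync_offset != 0.0:
        target = config.target_fs if config.target_fs is not None else recording.fs
        recording, poses = synchronize_and_resample(recording, poses, target, config.sync_offset)
    elif len(poses) != recording.n_samples:
        recording, poses = synchronize_and_resample(recording, poses, recording.fs, 0.0)
    if config.position_filter:
        filtered = butter_lowpass(
            poses.translations.T, recording.fs, config.position_filter_cutoff, config.position_filter_order
        ).T
        poses = RigidPoseSeries(poses.timestamps, poses.rotations, filtered)

    corrected, models = sliding_correct(
        recording,
        poses,
        array,
        l_max=config.l_max,
        window=config.window,
        step=config.step,
        prediction_filter=config.prediction_filter,
    )
    logger.info("pipeline: %d windows, l_max=%d", len(models.models), config.l_max)

    prediction = recording.data - corrected.data
    sf = shielding_factor_spectrum(recording, corrected)
    rr = rms_reduction(recording, corrected)
    report = {
        "provenance": {
            "harmfield_version": __version__,
            "numpy_version": np.__version__,
            "config": asdict(config),
            "config_digest": config.digest(),
            "seed": config.seed,
        },
        "n_windows": len(models.models),
        "window_s": models.window,
        "step_s": models.step,
        "condition_numbers": [m.condition_number for _, _, m in models.models],
        "r2_in_sample": r_squared(recording.data, prediction),
        "shielding_db_0hz_mean": float(sf["mean"][0]),
        "shielding_db_0hz_sem": float(sf["sem"][0]),
        "rms_reduction_pct_mean": rr["mean"],
        "rms_reduction_pct_sem": rr["sem"],
        "rms_reduction_pct_per_channel": rr["per_channel"].tolist(),
    }
    write_field_table(corrected, out_dir / "corrected.csv")
    models.to_json(out_dir / "models.json")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
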