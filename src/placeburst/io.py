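"""Session I/O: spike tables, position tracks, session descriptors, metric reports.

The canonical on-disk layout for one cell-session is three plain-text files:

* ``spikes.csv`` — columns ``time_s, amplitude`` (amplitude in the recording
  system's arbitrary units; required by the diminishing-amplitude burst rule);
* ``track.csv`` — columns ``time_s, x_cm, y_cm`` in an arena-centered frame
  (origin at the cylinder center), nominally sampled at 60 Hz;
* ``session.yaml`` — keys ``session_id, arena_radius_cm, card_angle_deg,
  duration_s``.

All times are seconds as decimals.  The arena-centered frame makes rotation
operations (cue-card protocols, rotation search) trivial.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    EmptyFileError,
    MissingColumnError,
    NonMonotonicTimeError,
    OutOfArenaError,
)

logger = logging.getLogger(__name__)

SPIKE_COLUMNS = ("time_s", "amplitude")
TRACK_COLUMNS = ("time_s", "x_cm", "y_cm")
DESCRIPTOR_KEYS = ("session_id", "arena_radius_cm", "card_angle_deg", "duration_s")


@dataclass(frozen=True)
class SessionDescriptor:
    """Metadata for one recording session in the cylindrical arena.

    ``card_angle_deg`` is the angular position of the local cue-card center,
    counter-clockwise positive, in [0, 360).
    """

    session_id: int
    arena_radius_cm: float
    card_angle_deg: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.arena_radius_cm <= 0:
            raise ValueError(f"arena_radius_cm must be > 0, got {self.arena_radius_cm}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if not (0.0 <= self.card_angle_deg < 360.0):
            raise ValueError(f"card_angle_deg must be in [0, 360), got {self.card_angle_deg}")


class SpikeTrain:
    """Ordered spike times (s) with per-spike peak amplitudes (arbitrary units)."""

    def __init__(self, times: np.ndarray, amplitudes: np.ndarray):
        times = np.asarray(times, dtype=float)
        amplitudes = np.asarray(amplitudes, dtype=float)
        if times.ndim != 1 or amplitudes.ndim != 1:
            raise ValueError("times and amplitudes must be 1-D")
        if len(times) != len(amplitudes):
            raise ValueError("times and amplitudes must have equal length")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise NonMonotonicTimeError("spike times must be strictly increasing")
        if np.any(amplitudes <= 0):
            raise ValueError("spike amplitudes must be positive")
        self.times = times
        self.amplitudes = amplitudes

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def subset(self, indices: np.ndarray) -> "SpikeTrain":
        """Sub-train at the given (sorted) spike indices."""
        idx = np.asarray(indices, dtype=int)
        return SpikeTrain(self.times[idx], self.amplitudes[idx])

    def isis_ms(self) -> np.ndarray:
        """Inter-spike intervals in milliseconds."""
        return np.diff(self.times) * 1000.0

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SpikeTrain)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.amplitudes, other.amplitudes)
        )

    def __repr__(self) -> str:
        return f"SpikeTrain(n={len(self)})"


class PositionTrack:
    """Timestamped 2-D head trajectory in cm, arena-centered frame."""

    def __init__(self, times: np.ndarray, x: np.ndarray, y: np.ndarray):
        times = np.asarray(times, dtype=float)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not (len(times) == len(x) == len(y)):
            raise ValueError("times, x, y must have equal length")
        if len(times) == 0:
            raise EmptyFileError("position track is empty")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise NonMonotonicTimeError("track times must be strictly increasing")
        self.times = times
        self.x = x
        self.y = y

    def __len__(self) -> int:
        return len(self.times)

    @property
    def sample_interval(self) -> float:
        """Median inter-sample interval in seconds (1/60 s nominally)."""
        if len(self.times) < 2:
            return 0.0
        return float(np.median(np.diff(self.times)))

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def nearest_sample(self, t: np.ndarray) -> np.ndarray:
        """Index of the temporally nearest track sample for each time in ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t)
        idx = np.clip(idx, 1, len(self.times) - 1)
        left = idx - 1
        use_left = (t - self.times[left]) <= (self.times[idx] - t)
        return np.where(use_left, left, idx)

    def position_at(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) of the temporally nearest track sample for each time."""
        idx = self.nearest_sample(t)
        return self.x[idx], self.y[idx]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PositionTrack)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
        )

    def __repr__(self) -> str:
        return f"PositionTrack(n={len(self)}, duration={self.duration:.1f}s)"


def _read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyFileError(f"{path}: file has no content") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise EmptyFileError(f"{path}: no data rows")
    return df


def read_spikes(path: str | Path) -> SpikeTrain:
    df = _read_table(path, SPIKE_COLUMNS)
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise NonMonotonicTimeError(f"{path}: spike times not strictly increasing")
    return SpikeTrain(t, df["amplitude"].to_numpy(dtype=float))


def read_track(path: str | Path, arena_radius_cm: float | None = None) -> PositionTrack:
    df = _read_table(path, TRACK_COLUMNS)
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise NonMonotonicTimeError(f"{path}: track times not strictly increasing")
    x = df["x_cm"].to_numpy(dtype=float)
    y = df["y_cm"].to_numpy(dtype=float)
    if arena_radius_cm is not None:
        r = np.hypot(x, y)
        bad = r > arena_radius_cm + 1e-9
        if np.any(bad):
            i = int(np.argmax(bad))
            raise OutOfArenaError(
                f"{path}: position ({x[i]:.2f}, {y[i]:.2f}) cm outside arena "
                f"radius {arena_radius_cm} cm (row {i})"
            )
    return PositionTrack(t, x, y)


def read_descriptor(path: str | Path) -> SessionDescriptor:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise EmptyFileError(f"{path}: descriptor is empty or malformed")
    missing = [k for k in DESCRIPTOR_KEYS if k not in raw]
    if missing:
        raise MissingColumnError(f"{path}: missing descriptor key(s) {missing}")
    return SessionDescriptor(
        session_id=int(raw["session_id"]),
        arena_radius_cm=float(raw["arena_radius_cm"]),
        card_angle_deg=float(raw["card_angle_deg"]),
        duration_s=float(raw["duration_s"]),
    )


def read_session(
    spike_path: str | Path, track_path: str | Path, descriptor_path: str | Path
) -> tuple[SpikeTrain, PositionTrack, SessionDescriptor]:
    """Load and validate one cell-session.

    Spikes outside [0, duration] are rejected (count logged).  Track positions
    must lie inside the arena.
    """
    desc = read_descriptor(descriptor_path)
    spikes = read_spikes(spike_path)
    track = read_track(track_path, arena_radius_cm=desc.arena_radius_cm)
    keep = (spikes.times >= 0.0) & (spikes.times <= desc.duration_s)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d spike(s) outside [0, %.1f] s", spike_path, n_dropped, desc.duration_s)
        spikes = SpikeTrain(spikes.times[keep], spikes.amplitudes[keep])
    return spikes, track, desc


def write_spikes(spikes: SpikeTrain, path: str | Path) -> None:
    pd.DataFrame({"time_s": spikes.times, "amplitude": spikes.amplitudes}).to_csv(path, index=False)


def write_track(track: PositionTrack, path: str | Path) -> None:
    pd.DataFrame({"time_s": track.times, "x_cm": track.x, "y_cm": track.y}).to_csv(path, index=False)


def write_descriptor(desc: SessionDescriptor, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(desc), fh, sort_keys=False)


def write_metrics_report(metrics: Sequence, path: str | Path, fieldnames: Sequence[str] | None = None) -> None:
    """Write one row per cell-session to a delimited report.

    Accepts dataclass instances, mappings, or a DataFrame.  Round-trips
    losslessly through :func:`read_metrics_report` (float repr precision).
    ``fieldnames`` fixes the header for an empty record list.
    """
    if isinstance(metrics, pd.DataFrame):
        df = metrics
    else:
        rows = [
            dataclasses.asdict(m) if dataclasses.is_dataclass(m) else dict(m)
            for m in metrics
        ]
        df = pd.DataFrame(rows, columns=list(fieldnames) if fieldnames and not rows else None)
    df.to_csv(path, index=False)


def read_metrics_report(path: str | Path) -> pd.DataFrame:
    """Read a metrics report written by :func:`write_metrics_report`."""
    return pd.read_csv(path)
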