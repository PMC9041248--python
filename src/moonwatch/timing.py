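"""Frame-timestamp logging and per-frame time reconstruction.

Interpreted-language capture loops make the nominal frame rate of the
recorded video unreliable, so a session writes periodic checkpoints of
(wall-clock time, cumulative frame count) and every per-frame time used
downstream is reconstructed from that log by piecewise-linear
interpolation — never from the container's advertised fps.

Log dialect: line-oriented plain text.  ``#``-prefixed header lines carry
``key=value`` camera settings plus the ISO-8601 session start; each body
line is ``<ISO-8601 wall time>\\t<cumulative frame count>``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import IO

import numpy as np

__all__ = [
    "TimestampLog",
    "append_checkpoint",
    "frame_time",
    "mean_frame_period",
    "write_log",
    "read_log",
    "TimestampLogWriter",
]

_EPOCH = datetime(2000, 1, 1, tzinfo=timezone.utc)


@dataclass
class TimestampLog:
    """Checkpoints of (seconds since session start, cumulative frame count)."""

    times_s: list[float] = field(default_factory=list)
    frame_counts: list[int] = field(default_factory=list)
    camera_settings: dict[str, str] = field(default_factory=dict)
    session_start: datetime = _EPOCH

    def __post_init__(self) -> None:
        if len(self.times_s) != len(self.frame_counts):
            raise ValueError("times and frame counts must be parallel")
        if self.frame_counts and self.frame_counts[0] != 0:
            raise ValueError("first checkpoint must be at frame 0")
        if np.any(np.diff(self.times_s) <= 0) or np.any(np.diff(self.frame_counts) <= 0):
            raise ValueError("checkpoints must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_s)

    @property
    def last_frame(self) -> int:
        return self.frame_counts[-1] if self.frame_counts else -1


def append_checkpoint(log: TimestampLog, t: float, frames: int) -> TimestampLog:
    """Append one (time, cumulative frame count) checkpoint in place.

    Rejects non-monotone input with a diagnostic ``ValueError``.
    """
    if log.times_s:
        if t <= log.times_s[-1]:
            raise ValueError(f"non-monotone checkpoint: t={t} after t={log.times_s[-1]}")
        if frames <= log.frame_counts[-1]:
            raise ValueError(
                f"non-monotone checkpoint: frames={frames} after {log.frame_counts[-1]}"
            )
    elif frames != 0:
        raise ValueError("first checkpoint must be at frame 0")
    log.times_s.append(float(t))
    log.frame_counts.append(int(frames))
    return log


def frame_time(log: TimestampLog, frame_index):
    """Capture time (seconds since session start) of a frame.

    Piecewise-linear interpolation of time against cumulative frame count;
    exact at checkpoints, strictly increasing in ``frame_index``.  Indices
    beyond the last checkpoint raise (no extrapolation).  Accepts scalars
    or arrays.
    """
    if len(log) < 2:
        raise ValueError("need at least two checkpoints to reconstruct times")
    idx = np.asarray(frame_index)
    if np.any(idx < 0) or np.any(idx > log.last_frame):
        raise ValueError(f"frame index out of checkpointed range [0, {log.last_frame}]")
    out = np.interp(idx, log.frame_counts, log.times_s)
    return float(out) if np.isscalar(frame_index) else out


def mean_frame_period(log: TimestampLog) -> float:
    """Session-mean seconds per frame, from first/last checkpoints."""
    if len(log) < 2:
        raise ValueError("need at least two checkpoints")
    return (log.times_s[-1] - log.times_s[0]) / (log.frame_counts[-1] - log.frame_counts[0])


def write_log(log: TimestampLog, path_or_file: str | Path | IO[str]) -> None:
    fh, close = _open(path_or_file, "w")
    try:
        fh.write(f"# session_start={log.session_start.isoformat()}\n")
        for key, val in log.camera_settings.items():
            fh.write(f"# {key}={val}\n")
        for t, n in zip(log.times_s, log.frame_counts):
            wall = log.session_start + timedelta(seconds=t)
            fh.write(f"{wall.isoformat()}\t{n}\n")
    finally:
        if close:
            fh.close()


def read_log(path_or_file: str | Path | IO[str]) -> TimestampLog:
    fh, close = _open(path_or_file, "r")
    try:
        settings: dict[str, str] = {}
        start: datetime | None = None
        times: list[float] = []
        frames: list[int] = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    if key.strip() == "session_start":
                        start = datetime.fromisoformat(val.strip())
                    else:
                        settings[key.strip()] = val.strip()
                continue
            wall_s, _, count_s = line.partition("\t")
            wall = datetime.fromisoformat(wall_s)
            if start is None:
                start = wall
            times.append((wall - start).total_seconds())
            frames.append(int(count_s))
        if start is None:
            start = _EPOCH
        return TimestampLog(times, frames, settings, start)
    finally:
        if close:
            fh.close()


class TimestampLogWriter:
    """Streaming checkpoint writer that flushes after every entry, so a
    crash loses at most one checkpoint interval."""

    def __init__(
        self,
        path: str | Path,
        session_start: datetime = _EPOCH,
        camera_settings: dict[str, str] | None = None,
    ) -> None:
        self.log = TimestampLog(
            camera_settings=dict(camera_settings or {}), session_start=session_start
        )
        self._fh: IO[str] = open(path, "w")
        self._fh.write(f"# session_start={session_start.isoformat()}\n")
        for key, val in self.log.camera_settings.items():
            self._fh.write(f"# {key}={val}\n")
        self._fh.flush()

    def checkpoint(self, t: float, frames: int) -> None:
        append_checkpoint(self.log, t, frames)
        wall = self.log.session_start + timedelta(seconds=float(t))
        self._fh.write(f"{wall.isoformat()}\t{int(frames)}\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "TimestampLogWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def _open(path_or_file, mode):
    if isinstance(path_or_file, (str, Path)):
        return open(path_or_file, mode), True
    if isinstance(path_or_file, io.IOBase) or hasattr(
        path_or_file, "write" if "w" in mode else "read"
    ):
        return path_or_file, False
    raise TypeError(f"cannot open {path_or_file!r}")
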