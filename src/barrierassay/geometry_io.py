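"""Track/arena data model, track table I/O, calibration, and animal-count estimation.

The canonical interchange format is a tidy long-form CSV with columns
``track_id, frame, time_s, x, y, units``.  A best-effort reader for a wide
per-animal-column export (``frame, time_s, <id>_x, <id>_y, ...``) is provided
for data coming from commercial trackers.

Coordinates are carried either in ``pixel`` or ``mm`` units; :func:`calibrate`
converts pixels to millimetres using the arena's pixel scale.  Frame indices
are authoritative; time is derived from the frame rate when absent.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    IntegrityError,
    ParseError,
    UnitError,
)

PIXEL = "pixel"
MM = "mm"
_UNIT_VALUES = (PIXEL, MM)

#: Default calibration: a 1024 px sensor imaging a ~47 mm field of view.
DEFAULT_PIXEL_SCALE = 47.0 / 1024.0
DEFAULT_FRAME_RATE = 3.0

_TIDY_COLUMNS = ["track_id", "frame", "time_s", "x", "y", "units"]


@dataclass(frozen=True)
class Arena:
    """Assay geometry and acquisition parameters, all lengths in mm.

    ``barrier_x`` is the barrier midline along the odor axis,
    ``dead_zone_halfwidth`` the half-width of the untrackable marker zone
    around it, and ``odor_direction`` declares which way along x the odor
    lies (``increasing_x`` or ``decreasing_x``).
    """

    fov_width: float = 47.0
    fov_height: float = 47.0
    pixel_scale: float | None = DEFAULT_PIXEL_SCALE
    frame_rate: float = DEFAULT_FRAME_RATE
    barrier_x: float = 23.5
    dead_zone_halfwidth: float = 1.5
    odor_direction: str = "increasing_x"
    bin_width: float = 1.0
    termination_margin: float = 1.0
    direction_window: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.barrier_x < self.fov_width):
            raise ConfigurationError(
                f"barrier_x={self.barrier_x} must lie strictly inside "
                f"(0, {self.fov_width})"
            )
        if self.dead_zone_halfwidth < 0:
            raise ConfigurationError("dead_zone_halfwidth must be >= 0")
        if self.bin_width <= 0:
            raise ConfigurationError("bin_width must be > 0")
        if self.pixel_scale is not None and self.pixel_scale <= 0:
            raise ConfigurationError("pixel_scale must be > 0")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be > 0")
        if self.odor_direction not in ("increasing_x", "decreasing_x"):
            raise ConfigurationError(
                f"odor_direction must be 'increasing_x' or 'decreasing_x', "
                f"got {self.odor_direction!r}"
            )
        if self.termination_margin < 0:
            raise ConfigurationError("termination_margin must be >= 0")
        if self.direction_window <= 0:
            raise ConfigurationError("direction_window must be > 0")

    @property
    def odor_sign(self) -> float:
        """+1 if the odor lies toward increasing x, else -1."""
        return 1.0 if self.odor_direction == "increasing_x" else -1.0

    def to_dict(self) -> dict:
        return {
            "fov_width": self.fov_width,
            "fov_height": self.fov_height,
            "pixel_scale": self.pixel_scale,
            "frame_rate": self.frame_rate,
            "barrier_x": self.barrier_x,
            "dead_zone_halfwidth": self.dead_zone_halfwidth,
            "odor_direction": self.odor_direction,
            "bin_width": self.bin_width,
            "termination_margin": self.termination_margin,
            "direction_window": self.direction_window,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Arena":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown arena fields: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Arena":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "arena" in data:
            data = data["arena"]
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"arena": self.to_dict()}, fh, sort_keys=True)


@dataclass(eq=False)
class Track:
    """One animal trajectory: ordered timestamped midpoints in one unit system."""

    track_id: str
    frame: np.ndarray
    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    units: str = PIXEL

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.frame.size
        if n < 1:
            raise IntegrityError(f"track {self.track_id!r} has no points")
        if not (self.time.size == self.x.size == self.y.size == n):
            raise IntegrityError(f"track {self.track_id!r} has ragged columns")
        if np.any(np.diff(self.frame) <= 0):
            raise IntegrityError(
                f"track {self.track_id!r}: frames must be strictly increasing"
            )
        if np.any(self.frame < 0):
            raise IntegrityError(f"track {self.track_id!r}: negative frame index")
        for name, arr in (("time", self.time), ("x", self.x), ("y", self.y)):
            if not np.all(np.isfinite(arr)):
                raise IntegrityError(
                    f"track {self.track_id!r}: non-finite {name} value"
                )
        if self.units not in _UNIT_VALUES:
            raise UnitError(f"track {self.track_id!r}: unknown units {self.units!r}")

    @property
    def n_points(self) -> int:
        return int(self.frame.size)

    @property
    def duration(self) -> float:
        """Elapsed time between first and last point, seconds."""
        return float(self.time[-1] - self.time[0])

    @property
    def x_span(self) -> float:
        return float(self.x.max() - self.x.min())

    @property
    def y_span(self) -> float:
        return float(self.y.max() - self.y.min())

    @property
    def bbox_area(self) -> float:
        return self.x_span * self.y_span

    @property
    def path_length(self) -> float:
        return float(np.sum(np.hypot(np.diff(self.x), np.diff(self.y))))


@dataclass(eq=False)
class TrackSet:
    """A collection of tracks from one experiment plus its arena."""

    tracks: list[Track]
    arena: Arena = field(default_factory=Arena)
    condition_label: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.tracks = list(self.tracks)
        ids = [t.track_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate track ids: {dup}")
        units = {t.units for t in self.tracks}
        if len(units) > 1:
            raise UnitError(f"mixed units within TrackSet: {sorted(units)}")

    @property
    def units(self) -> str | None:
        return self.tracks[0].units if self.tracks else None

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)


def tracks_equal(a: TrackSet, b: TrackSet, rtol: float = 1e-6) -> bool:
    """Coordinate-level equality to a relative tolerance (for round-trip checks)."""
    if len(a) != len(b):
        return False
    bm = {t.track_id: t for t in b}
    for ta in a:
        tb = bm.get(ta.track_id)
        if tb is None or ta.units != tb.units:
            return False
        if not np.array_equal(ta.frame, tb.frame):
            return False
        for u, v in ((ta.time, tb.time), (ta.x, tb.x), (ta.y, tb.y)):
            if not np.allclose(u, v, rtol=rtol, atol=1e-9):
                return False
    return True


# ---------------------------------------------------------------------------
# reading / writing


def _fail_bad_rows(mask: pd.Series, column: str, path: str | Path) -> None:
    if mask.any():
        # +2: one for the header, one for 0-based indexing
        line = int(mask.idxmax()) + 2
        raise ParseError(f"{path}: malformed value in column {column!r} at line {line}")


def _read_tidy(path: str | Path, arena: Arena) -> list[Track]:
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in ("track_id", "frame", "x", "y") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if df.empty:
        return []
    frame = pd.to_numeric(df["frame"], errors="coerce")
    _fail_bad_rows(frame.isna(), "frame", path)
    x = pd.to_numeric(df["x"], errors="coerce")
    _fail_bad_rows(x.isna(), "x", path)
    y = pd.to_numeric(df["y"], errors="coerce")
    _fail_bad_rows(y.isna(), "y", path)
    if "time_s" in df.columns:
        time = pd.to_numeric(df["time_s"], errors="coerce")
        _fail_bad_rows(time.isna() & df["time_s"].notna(), "time_s", path)
        time = time.fillna(frame / arena.frame_rate)
    else:
        time = frame / arena.frame_rate
    if "units" in df.columns:
        units_col = df["units"].fillna(PIXEL)
        bad = ~units_col.isin(_UNIT_VALUES)
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ParseError(f"{path}: unknown units value at line {line}")
    else:
        units_col = pd.Series(PIXEL, index=df.index)

    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        i = int(dup.idxmax())
        raise IntegrityError(
            f"{path}: duplicate (track_id, frame) = "
            f"({df['track_id'].iloc[i]!r}, {df['frame'].iloc[i]}) at line {i + 2}"
        )

    work = pd.DataFrame(
        {
            "track_id": df["track_id"],
            "frame": frame.astype(np.int64),
            "time": time.astype(float),
            "x": x.astype(float),
            "y": y.astype(float),
            "units": units_col,
        }
    )
    tracks: list[Track] = []
    for tid, grp in work.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        tunits = grp["units"].unique()
        if len(tunits) > 1:
            raise IntegrityError(f"{path}: track {tid!r} mixes units {list(tunits)}")
        tracks.append(
            Track(
                track_id=str(tid),
                frame=grp["frame"].to_numpy(),
                time=grp["time"].to_numpy(),
                x=grp["x"].to_numpy(),
                y=grp["y"].to_numpy(),
                units=str(tunits[0]),
            )
        )
    return tracks


_WIDE_COORD = re.compile(r"^(?P<tid>.+?)[\s_](?P<axis>[xy])$", re.IGNORECASE)


def _read_wide(path: str | Path, arena: Arena) -> list[Track]:
    """Wide per-animal-column layout: frame[, time_s], <id>_x, <id>_y, ...

    Blank cells mean the animal was not tracked at that frame.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if "frame" not in df.columns:
        raise ParseError(f"{path}: wide dialect requires a 'frame' column")
    pairs: dict[str, dict[str, str]] = {}
    for col in df.columns:
        if col in ("frame", "time_s", "units"):
            continue
        m = _WIDE_COORD.match(col)
        if not m:
            raise ParseError(f"{path}: cannot interpret wide column {col!r}")
        pairs.setdefault(m.group("tid"), {})[m.group("axis").lower()] = col
    frame = pd.to_numeric(df["frame"], errors="coerce")
    _fail_bad_rows(frame.isna(), "frame", path)
    frame = frame.astype(np.int64)
    if frame.duplicated().any():
        i = int(frame.duplicated().idxmax())
        raise IntegrityError(f"{path}: duplicate frame {frame.iloc[i]} at line {i + 2}")
    if "time_s" in df.columns:
        time = pd.to_numeric(df["time_s"], errors="coerce")
    else:
        time = frame / arena.frame_rate
    units = PIXEL
    if "units" in df.columns and df["units"].notna().any():
        units = str(df["units"].dropna().iloc[0])
    tracks: list[Track] = []
    for tid, axes in pairs.items():
        if set(axes) != {"x", "y"}:
            raise ParseError(f"{path}: animal {tid!r} lacks an x or y column")
        xs = pd.to_numeric(df[axes["x"]], errors="coerce")
        ys = pd.to_numeric(df[axes["y"]], errors="coerce")
        keep = xs.notna() & ys.notna()
        if not keep.any():
            continue
        order = np.argsort(frame[keep].to_numpy(), kind="stable")
        tracks.append(
            Track(
                track_id=str(tid),
                frame=frame[keep].to_numpy()[order],
                time=time[keep].to_numpy(dtype=float)[order],
                x=xs[keep].to_numpy(dtype=float)[order],
                y=ys[keep].to_numpy(dtype=float)[order],
                units=units,
            )
        )
    return tracks


def read_tracks(
    path: str | Path,
    dialect: str = "tidy_csv",
    arena: Arena | None = None,
    condition_label: str = "",
) -> TrackSet:
    """Read a track table into a :class:`TrackSet`.  No filtering is applied.

    Parameters
    ----------
    path:
        CSV file to read.
    dialect:
        ``"tidy_csv"`` (canonical long form) or ``"wormlab_wide"``
        (one x/y column pair per animal).
    arena:
        Arena attached to the returned set; defaults to :class:`Arena()`.
    """
    arena = arena or Arena()
    if dialect == "tidy_csv":
        tracks = _read_tidy(path, arena)
    elif dialect == "wormlab_wide":
        tracks = _read_wide(path, arena)
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    return TrackSet(
        tracks=tracks, arena=arena, condition_label=condition_label, source=str(path)
    )


def write_tracks(track_set: TrackSet, path: str | Path) -> None:
    """Write a TrackSet as tidy CSV.  ``read_tracks`` inverts this exactly
    (coordinates to 10 significant digits); output is byte-stable."""
    rows = []
    for t in track_set:
        rows.append(
            pd.DataFrame(
                {
                    "track_id": t.track_id,
                    "frame": t.frame,
                    "time_s": t.time,
                    "x": t.x,
                    "y": t.y,
                    "units": t.units,
                }
            )
        )
    if rows:
        df = pd.concat(rows, ignore_index=True)
    else:
        df = pd.DataFrame(columns=_TIDY_COLUMNS)
    try:
        df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    except OSError as exc:
        raise ParseError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# calibration and animal count


def calibrate(track_set: TrackSet) -> TrackSet:
    """Convert pixel coordinates to mm using ``arena.pixel_scale``.

    Frame and time columns are preserved exactly.  A TrackSet already in mm
    is returned unchanged (idempotent).
    """
    if track_set.units in (None, MM):
        return track_set
    scale = track_set.arena.pixel_scale
    if scale is None:
        raise ConfigurationError("calibrate requires arena.pixel_scale")
    new_tracks = [
        Track(
            track_id=t.track_id,
            frame=t.frame.copy(),
            time=t.time.copy(),
            x=t.x * scale,
            y=t.y * scale,
            units=MM,
        )
        for t in track_set
    ]
    return TrackSet(
        tracks=new_tracks,
        arena=track_set.arena,
        condition_label=track_set.condition_label,
        source=track_set.source,
    )


def estimate_animal_count(track_set: TrackSet) -> int:
    """Maximum number of simultaneous tracks present in any single frame."""
    if not len(track_set):
        return 0
    counts: dict[int, int] = {}
    for t in track_set:
        for f in t.frame:
            counts[int(f)] = counts.get(int(f), 0) + 1
    return max(counts.values())
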