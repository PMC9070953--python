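"""Residence-probability and velocity profiles versus distance from the barrier.

Distances are signed along the odor axis (negative = origin side) and binned
into half-open 1-mm bins [left, right) with edges on integer mm relative to
the barrier.  Residence probability is the fraction of all tracked midpoints
falling in each bin; velocity is the Euclidean displacement over a centred
2-s window divided by the window length, in um/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyProfileError, UnitError
from .geometry_io import MM, Arena, Track, TrackSet

MM_TO_UM = 1000.0


def default_bin_edges(arena: Arena) -> np.ndarray:
    """Integer-mm bin edges (signed distance) covering the field of view."""
    ends = np.array([0.0 - arena.barrier_x, arena.fov_width - arena.barrier_x])
    ends *= arena.odor_sign
    lo, hi = math.floor(ends.min()), math.ceil(ends.max())
    return np.arange(lo, hi + arena.bin_width / 2, arena.bin_width, dtype=float)


def signed_distance(track_set: TrackSet, arena: Arena | None = None) -> dict[str, np.ndarray]:
    """Per-point signed distance from the barrier, mm, keyed by track id.

    Positive values lie toward the odor side regardless of ``odor_direction``.
    """
    arena = arena or track_set.arena
    if track_set.units not in (None, MM):
        raise UnitError("signed_distance requires mm-calibrated tracks")
    return {
        t.track_id: (t.x - arena.barrier_x) * arena.odor_sign for t in track_set
    }


def _bin_of(values: np.ndarray, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Half-open [left, right) bin index per value, plus an in-range mask."""
    idx = np.searchsorted(edges, values, side="right") - 1
    ok = (idx >= 0) & (idx < edges.size - 1) & (values < edges[-1])
    return idx, ok


@dataclass(eq=False)
class ResidenceProfile:
    bin_edges: np.ndarray
    probabilities: np.ndarray
    counts: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left_mm": self.bin_edges[:-1],
                "bin_right_mm": self.bin_edges[1:],
                "probability": self.probabilities,
                "n": self.counts,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


@dataclass(eq=False)
class VelocityProfile:
    bin_edges: np.ndarray
    mean_velocity: np.ndarray  # um/s; NaN where n_samples == 0
    n_samples: np.ndarray
    sem: np.ndarray  # um/s; NaN where n_samples < 2

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left_mm": self.bin_edges[:-1],
                "bin_right_mm": self.bin_edges[1:],
                "mean_velocity_um_s": self.mean_velocity,
                "n": self.n_samples,
                "sem_um_s": self.sem,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


def residence_probability(
    track_set: TrackSet,
    arena: Arena | None = None,
    bin_edges: np.ndarray | None = None,
) -> ResidenceProfile:
    """Fraction of all tracked midpoints in each 1-mm signed-distance bin.

    Every midpoint of every track at every frame contributes exactly once;
    normalization is over the midpoints inside the binned range.
    """
    arena = arena or track_set.arena
    edges = np.asarray(
        default_bin_edges(arena) if bin_edges is None else bin_edges, dtype=float
    )
    dists = signed_distance(track_set, arena)
    counts = np.zeros(edges.size - 1, dtype=np.int64)
    for s in dists.values():
        idx, ok = _bin_of(s, edges)
        counts += np.bincount(idx[ok], minlength=edges.size - 1)
    total = counts.sum()
    if total == 0:
        raise EmptyProfileError("no tracked midpoints inside the binned range")
    return ResidenceProfile(
        bin_edges=edges, probabilities=counts / total, counts=counts
    )


def instantaneous_velocity(
    track: Track, window: float = 2.0, frame_rate: float | None = None
) -> np.ndarray:
    """Centred-window Euclidean velocity per point, um/s; NaN where undefined.

    v(t) = ||position(t + window/2) - position(t - window/2)|| / window.
    A sample is defined only when the exact frames at +/- window/2 exist in
    the track (gaps are not silently bridged) and the point is at least
    window/2 from either track end.
    """
    if track.units != MM:
        raise UnitError("instantaneous_velocity requires mm-calibrated tracks")
    if window <= 0:
        raise ConfigurationError("window must be > 0")
    if frame_rate is None:
        if track.n_points > 1 and track.time[-1] > track.time[0]:
            frame_rate = (track.frame[-1] - track.frame[0]) / (
                track.time[-1] - track.time[0]
            )
        else:
            raise ConfigurationError("frame_rate is required for single-point tracks")
    half = window * frame_rate / 2.0
    k = int(round(half))
    if abs(half - k) > 1e-6 or k < 1:
        raise ConfigurationError(
            f"window/2 = {window / 2} s is not a whole number of frames "
            f"at {frame_rate} fps"
        )
    frames = track.frame
    v = np.full(track.n_points, np.nan)

    def _locate(target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pos = np.searchsorted(frames, target)
        ok = pos < frames.size
        pos_c = np.clip(pos, 0, frames.size - 1)
        ok &= frames[pos_c] == target
        return pos_c, ok

    lo_idx, lo_ok = _locate(frames - k)
    hi_idx, hi_ok = _locate(frames + k)
    ok = lo_ok & hi_ok
    disp = np.hypot(
        track.x[hi_idx] - track.x[lo_idx], track.y[hi_idx] - track.y[lo_idx]
    )
    v[ok] = disp[ok] * MM_TO_UM / window
    return v


def velocity_profile(
    track_set: TrackSet,
    arena: Arena | None = None,
    window: float | None = None,
    bin_edges: np.ndarray | None = None,
    exclude_dead_zone: bool = False,
) -> VelocityProfile:
    """Mean +/- SEM of instantaneous velocity per 1-mm signed-distance bin.

    Each defined velocity sample is assigned to the bin of its central
    point's signed distance.  ``exclude_dead_zone`` drops samples whose
    central point lies within the untrackable zone itself.
    """
    arena = arena or track_set.arena
    window = arena.direction_window if window is None else window
    edges = np.asarray(
        default_bin_edges(arena) if bin_edges is None else bin_edges, dtype=float
    )
    nb = edges.size - 1
    sums = np.zeros(nb)
    sq_sums = np.zeros(nb)
    n = np.zeros(nb, dtype=np.int64)
    dists = signed_distance(track_set, arena)
    for t in track_set:
        v = instantaneous_velocity(t, window=window, frame_rate=arena.frame_rate)
        s = dists[t.track_id]
        ok = np.isfinite(v)
        if exclude_dead_zone:
            ok &= np.abs(s) > arena.dead_zone_halfwidth
        idx, in_range = _bin_of(s, edges)
        ok &= in_range
        idx, v = idx[ok], v[ok]
        np.add.at(sums, idx, v)
        np.add.at(sq_sums, idx, v * v)
        n += np.bincount(idx, minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
        var = np.where(
            n > 1, (sq_sums - n * mean**2) / np.maximum(n - 1, 1), np.nan
        )
        var = np.clip(var, 0.0, None)  # guard fp cancellation
        sem = np.where(n > 1, np.sqrt(var / np.maximum(n, 1)), np.nan)
    return VelocityProfile(bin_edges=edges, mean_velocity=mean, n_samples=n, sem=sem)
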